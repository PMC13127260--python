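# seegbci

Broadband motor screening and closed-loop 1-D cursor BCI simulation for
stereo-EEG (sEEG) depth-electrode recordings.

Stereo-EEG samples local field potentials volumetrically through depth
electrode leads.  During movement, cortical populations near the recording
site show a *broadband* power increase (here quantified over 65–115 Hz, a
range that sits above most oscillations and between the 60/120 Hz line-noise
harmonics) together with suppression of low-frequency rhythms.  This package
implements, end to end and on synthetic data, the computational pipeline of
an sEEG motor-BCI experiment:

1. **Synthetic data** — 1/f-distributed sEEG background with movement-locked
   broadband gain on somatotopically tuned channels, 20 Hz oscillation with
   movement suppression, 60/120 Hz line noise, and burst-like surface EMG;
   shuffled block-design task schedules; lognormal subject band-power models.
2. **Preprocessing** — bipolar re-referencing (adjacent same-lead,
   same-segment contact pairs) and automated movement epoching from the
   rectified 25–400 Hz EMG envelope (median + k·MAD threshold).
3. **Spectral estimation** — per-trial Welch spectra (1 s Hann windows, 0.5 s
   overlap, 1–300 Hz at 1 Hz), normalization to the global mean spectrum
   across all trials, band power, and an online Burg autoregressive band-power
   estimator at a 10 Hz update rate.
4. **Screening** — the signed point-biserial r² per bipolar channel and
   movement modality,

       r²± = sign(mean(P_move) − mean(P_rest)) · corr(P, label)²,

   computed on log band powers with movement trials compared only against the
   rest periods that follow the same movement type (controlling post-movement
   beta rebound); top channels become feedback control channels.
5. **Closed loop** — the 1-D cursor engine: v = κ·g·(P − P0) with P0 the mean
   and g the inverse standard deviation of a 30 s calibration buffer (adapted
   through run 0, frozen afterwards), 10 Hz updates, 5 s trial timeout, 3 s
   inter-trial interval, 2-minute runs.  Hits/misses/timeouts are scored the
   way the protocol scores them: accuracy = hits/(hits+misses), timeouts
   excluded; a condition is successful when the final two runs average > 80%.
6. **Cohort analytics** — tallies and trials-vs-accuracy Pearson correlations
   over a shipped 27-subject/31-condition reference table, plus per-run
   separation (d′) and learning rasters for simulated sessions.

## Worked example

```python
from seegbci import (SubjectModel, run_session, learning_curve,
                     final_two_run_accuracy)

model = SubjectModel.from_dprime(0.5, learning_rate=0.5, seed=0)
logs = run_session(model, n_runs=6, seed=0)          # run 0 calibrates
print(learning_curve(logs)[["run_index", "dprime", "accuracy_pct"]])
print(f"final two runs: {final_two_run_accuracy(logs):.1f}%")
```

```
   run_index    dprime  accuracy_pct
0          1  3.739183    100.000000
1          2  4.953790    100.000000
2          3  6.019029    100.000000
3          4  9.358169    100.000000
4          5  9.717361     88.888889
final two runs: 94.4%
```

The subject starts barely separable (d′ = 0.5 between active and rest log
band power) and gains one pooled standard deviation of separation per run.
The d′ column — the separation of per-trial mean powers between the two
target classes, amplified relative to the model d′ because each trial
averages tens of power samples — grows run over run, the feedback-learning
signature; accuracy counts only decided (non-timeout) trials and the final
two runs clear the 80% success criterion.

The same pipeline is scriptable from the shell:

```bash
seegbci simulate --seed 0 --outdir out      # recording + events + electrodes
seegbci screen   --indir out --outdir out   # bipolar map + control channels
seegbci loop     --seed 0 --outdir out      # closed-loop session + accuracy
seegbci report   --outdir out               # cohort tallies + correlations
```

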