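# Methods

This note records the models, conventions and numerical choices behind
`seegbci`, and what the synthetic-data pipeline does and does not establish
about real recordings.

## Signal model of the synthetic sEEG

Each sEEG channel is built from spectrally shaped Gaussian noise: white noise
is filtered in the frequency domain with |H(f)| ∝ f^(−χ/2), giving a power
spectrum ∝ f^(−χ) with direct control of the power-law exponent (default
χ = 2, the conventional local-field-potential scale).  The shaped noise is
split at 65 Hz into a low and a high component; on channels carrying a
somatotopy label, the high component's amplitude is multiplied by
√(broadband gain) during that modality's movement trials, with 100 ms
raised-cosine ramps at trial edges so Welch windows see no step
discontinuities.  The default broadband power gain is 3: the printed figures
of pericentral channels show movement-trial spectra sitting clearly above
rest across the high-frequency range, and a threefold band-power increase
reproduces that separation at 20 + 20 trials without making screening
trivial at the single-trial level.  No published value exists for this gain;
it is a generator convention, chosen once.

A 20 Hz amplitude-modulated sinusoid stands in for the sensorimotor rhythm
(amplitude ×0.5 during movement — qualitative oscillatory suppression), and
pure sinusoids at 60 Hz and 120 Hz (half amplitude) model line noise.  The
65–115 Hz analysis band excludes both harmonics by construction, which the
tests verify by toggling the line term.  No notch filtering is applied
anywhere: the 90–130 Hz feedback band deliberately spans 120 Hz, and the
bipolar montage is the only line-noise defence, as in the modelled protocol.

Surface EMG is band-limited (25–400 Hz) noise whose envelope rises 150 ms
after each movement cue (a reaction lag), modulated at the 1 Hz movement
pacing with a 0.3 floor so the burst never dips to baseline, over a small
baseline activity.  This is rich enough to exercise rectification and
threshold epoching; it does not model motor-unit physiology.

Electrode geometry uses a 3.5 mm centre-to-centre contact pitch (2 mm
contact length plus 1.5 mm inter-contact gap).  Positions are abstract
millimetre coordinates; nothing anatomical is modelled.

## Task schedule

Default screening block design: 20 trials per movement modality, 3 s each,
every movement followed by a 3 s rest annotated with the movement type it
follows.  Movement order is shuffled by seed.  Sample intervals are 0-based
and half-open.  Sampling rates default to 1200 Hz for screening and 2400 Hz
for feedback-band streaming, both configurable.

## Preprocessing

Bipolar channels pair contacts that are adjacent (consecutive contact
indices), on the same lead, and in the same lead segment; the derived
channel sits at the contact midpoint.  Re-referencing is exactly linear, so
common-mode components cancel to machine precision.

EMG epoching replaces manual demarcation: the rectified zero-phase-filtered
envelope is smoothed with a 50 ms moving average (a rectified carrier
crosses zero every half-cycle, so unsmoothed samples cannot stay above any
threshold), then thresholded at the rest-period median + k·MAD (k = 5,
minimum supra-threshold duration 200 ms).  Onsets may move at most 0.5 s
before the cue and never past the cue offset.  Zero-phase filtering is used
so envelope timing, and hence epoch boundaries, are unbiased.  Trials with
no supra-threshold run are flagged and excluded downstream.

## Spectra and band power

Per-trial spectra are Welch averaged periodograms: 1 s Hann windows, 0.5 s
overlap, evaluated on the 1–300 Hz grid at 1 Hz; only full windows inside a
(refined) trial are used, so partial tails never bias a trial differently
from another.  Each trial's spectrum is divided by the arithmetic mean
spectrum over all trials (movement and rest pooled), which removes the 1/f
dominance; after normalization every frequency column averages exactly 1.
Band power is the arithmetic mean of the bins on a closed interval
([65, 115] → 51 bins).  Statistics downstream consume natural-log band
powers by default (band power is multiplicative noise; the log stabilizes
variance) — exposed as a switch.

The online estimator fits a Burg autoregressive model (order 16, 0.5 s
windows — the conventional real-time BCI scale; neither value has a
published source) and averages the model spectrum over the feedback band on
the same 1 Hz grid, at a 10 Hz hop.  Multiple control channels are
arithmetic-mean combined.

## Screening statistic

The channel map is the signed point-biserial r²: pool a channel's per-trial
log band powers for one modality's movement trials and their same-type
following rest trials, correlate against class membership, square, and sign
by the direction of the mean difference.  The statistic is invariant to
common positive-affine transforms and antisymmetric under group exchange.
Movement trials are compared only with rest periods following the same
movement type, so post-movement (beta rebound) effects of *other* modalities
never leak into a comparison.  No multiple-testing correction is applied for
channel selection (none is applied in the modelled protocol); a
label-permutation null of the map-wide maximum is provided as a diagnostic.
Ties in selection break lexicographically by channel id.

A statistic computed on the two *mean spectra* alone would have no
trial-level variance to correlate against; the trial-wise point-biserial
form is the standard operationalization of signed r² maps in
electrocorticographic BCI and is the one implemented.

## Subject model and the closed loop

A subject is a two-state lognormal model of control-channel band power: log
power is normal with state-dependent mean (active vs passive/rest) and
common default sd 0.5.  The separation d′ = Δμ/σ parameterizes ability;
`learning_rate` adds to the active mean per completed run, growing d′ across
a session.  During a session the unit-variance innovation follows an AR(1)
process with lag-1 correlation 0.8: successive 0.5 s estimator windows at
the 10 Hz update rate share 80% of their samples, so consecutive online
band-power estimates are strongly correlated.  The marginal distribution per
state is unchanged (each draw is still the specified lognormal).  State
switches take effect after a 0.3 s reaction latency.  Without this
autocorrelation a null subject's cursor would diffuse an order of magnitude
too little to ever reach a target, making chance-level behaviour
unmeasurable.

Control law: v = κ·g·(P − P0), with P0 the calibration-buffer mean and
g the inverse buffer standard deviation (population variance, the streaming
convention; switchable).  κ = 0.1 screen units/s per unit z-score — no
screen calibration is published; this default makes a sustained
one-standard-deviation activation traverse the 0.4 screen units from centre
to target edge in 4 s, comfortably inside the 5 s timeout.  The cursor is a
point on [0, 1] starting at 0.5, clipped at the edges, updated at 10 Hz;
targets are the top (active) and bottom (passive) 10% bands.  Entering the
cued band is a hit, the opposite band a miss, and 5 s without either a
timeout — timeouts never enter the accuracy denominator.  Run 0 alternates
active/passive targets while P0/g are recomputed every update from the
trailing 30 s of power samples, then the normalizer freezes for the rest of
the session; run 0 is never scored.  Scoring runs pseudo-randomize targets
in balanced pairs, so any prefix of a run is balanced to ±1.  Each 2-minute
run packs as many (2 s display + ≤5 s trial + 3 s ITI) cycles as fit.

## Learning curves and d′

`learning_curve` summarizes each scoring run by the mean log trial power per
target class and standardizes the class separation to d′.  The default
denominator pools within-class variance across *all* scoring runs of the
session: under the subject model the trial-power variance is stationary and
only the means move, and a per-run sd estimated from ≤ 10 trials per class
is so noisy that the resulting d′ sequence is dominated by denominator
noise rather than the learning signal.  `per_run_sd=True` restores run-local
pooling for the conventional per-run definition.  When the pooled sd
degenerates (identical trial powers) d′ is capped at a configurable maximum
(default 50, far above any estimate arising from data).  Runs with fewer
than two trials in either class get a null d′.

Note that d′ computed on per-trial mean powers is amplified relative to the
model's per-sample d′ (each trial averages tens of autocorrelated samples),
so learning-curve values in the teens are expected and legitimate.

## Cohort analytics

The shipped condition table (one row per subject × feedback condition, 32
rows, 31 with an overt accuracy) is the package's reference cohort.  Success
is strict: accuracy > 80% (no row sits exactly at 80, so ≥ vs > does not
change any count).  Anatomy is tallied twice: exact precentral-gyrus labels,
and any label containing "PCG" (composites like "PCG/CIN" and boundary codes
like "PCG*" included).  The imagery success count in the table (11
conditions > 80%) differs from one summary count in the source material
(12); the tally is reported as computed, not asserted to either figure.

The trials-vs-accuracy Pearson correlation is computed under three pairings
— per condition, per subject at peak imagery accuracy, and per subject with
trials summed across conditions — because the published pairing is
ambiguous; all three are reported side by side and none is privileged.

## Problem sizes and verification

The test suite and acceptance script use: 50 seeded sessions for
accuracy-band checks (ideal d′ = 4 responder vs null d′ = 0, one calibration
run plus four scoring runs each), 20 seeds for planted-channel recovery
(gain 3, 20 + 20 trials, 16 contacts) and for learning monotonicity
(d′ 0.5 + 1.0 per run, five scoring runs), 100-permutation nulls over
54-channel null recordings, and 300-sample calibration buffers.  Null-model
chance behaviour is assessed on accuracy pooled over all decided trials of
all seeds, since single null sessions decide too few trials for a stable
per-session percentage.  Oracle equivalences (Welch vs explicit periodogram
averaging, signed r² and Pearson vs explicit sums, montage vs brute-force
enumeration) hold to 1e-10/1e-12.

## Limitations

Passing tests on this generator demonstrate the correctness of the
computations, not the physiology of real sEEG: the background is Gaussian
and stationary, broadband gain is constant within a trial, there are no
artifacts, no epileptiform activity, no electrode drift, and the subject
model reduces behaviour to a two-state lognormal process.  Misses are
defined geometrically (entering the wrong target band); the modelled
protocol distinguishes hits, misses and unconsidered trials without
publishing a miss mechanism.  Horizontal target layouts are mapped onto the
same single axis.  No anatomical localization, imaging, or real-time
hardware interoperability is attempted.
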