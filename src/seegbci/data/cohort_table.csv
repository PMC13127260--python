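subject_id,age,sex,hand,n_contacts,n_leads,side,modality_code,anatomy_code,anatomy_is_pcg_exact,overt_accuracy_pct,imagery_accuracy_pct,learning_trials
1,10,F,R,198,14,L,,,False,,,
2,16,F,L,217,14,B,T/RF,PCG,True,100,93,79
3,17,F,R,168,13,R,LH,PCG,True,95,97.5,69
4,18,M,L,231,14,R,LH,PCG,True,100,89.5,32
5,15,F,R,159,10,L,RH,PCG,True,100,50,19
5,15,F,R,159,10,L,RH/T,PCG,True,95,75.5,134
6,13,M,R,196,13,R,H/F,PCG/CIN,False,100,73,24
7,15,M,L,185,12,L,RH,AA,False,100,47.5,42
7,15,M,L,185,12,L,RH,AA,False,83.5,50,93
8,36,F,R,199,14,B,T/F,PCG,True,100,45,34
8,36,F,R,199,14,B,H/F,PCG,True,96,86,18
9,8,F,R,230,17,B,RH,PCG,True,90,,
10,19,M,R,211,15,B,RH,CS*,False,100,36,19
11,6,M,R,193,13,R,LH,PCG,True,100,,
12,37,M,R,237,15,B,T,CS/PoCG,False,100,45,0
13,15,M,R,215,16,B,LH,PCG,True,100,100,0
14,35,M,R,252,15,B,RH,PCG,True,100,100,26
15,17,F,R,232,15,B,RH,PCG,True,90.5,,
16,36,M,B,195,15,R,LH,OPC,False,100,84,143
17,12,F,R,232,16,B,LH,CS*,False,100,66,9
18,16,M,R,254,16,R,LH,PCG,True,96,100,6
19,46,F,L,256,13,B,RH,PCG,True,100,55,0
20,31,F,L,236,15,B,LF,PCG/CIN,False,94,74.5,41
21,16,M,R,241,16,B,RH,PCG,True,100,100,0
22,15,M,L,218,15,L,T,SCL/PoCG,False,100,76,26
23,16,F,R,255,15,B,RH,PCG/CIN,False,85,84,0
24,15,M,R,255,15,B,LH,WM,False,50,,
25,21,M,B,201,12,L,RH,PCG,True,91,,
26,18,M,R,230,16,L,RH,PCG*,False,96,90.5,0
26,18,M,R,230,16,L,RH,PCG,True,61.5,,
27,15,F,R,166,13,R,LH,PCG,True,100,,
27,15,F,R,166,13,R,LF,PCG,True,100,61,41
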