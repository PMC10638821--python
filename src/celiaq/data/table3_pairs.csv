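# Paired duodenal-biopsy dataset: 28 matched pairs captured before and after
# dietary gluten restriction, with the central modified Marsh grade and the
# continuous machine learning score (MLS) for each biopsy.
# Columns: pair_id, pre_marsh, post_marsh, pre_mls, post_mls.
# Note: pair 3 post_mls is 0.11; the source table cell carries a typographic
# stray character ("0.11 4") that is dropped here.
pair_id,pre_marsh,post_marsh,pre_mls,post_mls
1,3b,0,3.95,1.63
2,3a,0,0.82,-0.20
3,3b,0,2.44,0.11
4,3b,1,2.22,0.21
5,3a,3a,2.46,3.49
6,3b,0,3.78,-0.21
7,3b,0,2.85,1.52
8,3a,0,2.65,0.02
9,3b,0,2.44,1.15
10,1,0,1.57,0.78
11,3b,3a,3.48,1.65
12,3b,0,3.56,0.61
13,3b,1,2.80,1.51
14,3a,0,3.56,0.56
15,3a,0,1.27,0.55
16,2,1,2.28,0.93
17,3b,0,2.36,1.65
18,3b,0,4.28,0.40
19,3a,0,2.60,0.00
20,3b,0,1.70,0.98
21,3c,3b,3.71,1.70
22,3a,0,1.80,0.78
23,3b,0,3.06,-1.23
24,3b,0,2.96,0.71
25,3a,0,2.51,0.47
26,3b,0,3.38,0.87
27,3b,3a,3.02,1.96
28,3b,0,3.13,1.13
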