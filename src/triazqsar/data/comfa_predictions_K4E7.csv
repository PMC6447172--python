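id,experiment,prediction
1,9.432,9.120
2,8.678,8.786
3,7.686,7.746
4,6.431,6.429
5,9.569,9.031
6,9.569,9.361
7,9.602,9.397
8,9.328,8.894
9,6.301,6.442
10,9.284,9.455
11,9.469,9.462
12,9.456,9.871
13,9.337,9.212
14,9.337,9.776
15,9.310,9.527
16,8.434,8.497
17,6.731,6.721
18,6.731,6.362
19,6.301,6.931
20,6.301,6.266
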