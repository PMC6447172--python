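id,experiment,prediction
1,9.032,9.056
2,8.222,8.405
3,6.635,6.846
4,7.815,7.297
5,9.056,8.641
6,9.131,8.763
7,9.076,9.393
8,8.903,8.713
9,7.987,7.878
10,9.155,9.492
11,9.155,9.276
12,9.032,8.811
13,8.991,9.147
14,9.155,9.108
15,8.991,9.016
16,7.731,7.406
17,6.635,7.039
18,6.635,6.950
19,6.301,6.529
20,6.301,6.170
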