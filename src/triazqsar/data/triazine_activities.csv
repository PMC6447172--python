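id,name,cr_S2,cr_K4E7,ic50_S2,ic50_K4E7
1,"2-chloro-4-isopropylamino-6-ethylamino-1,3,5-triazine (atrazine)",100,100,0.93,0.37
2,"2-chloro-4-isopropylamino-6-amino-1,3,5-triazine (deethylatrazine)",15,18,6.0,2.1
3,"2-chloro-4-ethylamino-6-amino-1,3,5-triazine (deisopropylatrazine)",0.4,1.8,232,20.6
4,"2-hydroxy-4-isopropylamino-6-ethylamino-1,3,5-triazine (hydroxyatrazine)",6,0.1,15.3,371
5,"2-chloro-4-anilino-6-isopropylamino-1,3,5-triazine",106,140,0.88,0.27
6,"2-chloro-4-(3',4'-dimethoxyanilino)-6-isopropylamino-1,3,5-triazine",126,140,0.74,0.27
7,"2-chloro-4-(3',4'-dimethoxybenzylamino)-6-isopropylamino-1,3,5-triazine",109,148,0.84,0.25
8,"2-chloro-4-(3'-hydroxy-4'-methoxyanilino)-6-isopropylamino-1,3,5-triazine",74,79,1.25,0.47
9,"2-chloro-4-(2'-carboxy-4',5'-dimethoxyanilino)-6-isopropylamino-1,3,5-triazine",9,<0.1,10.3,>500
10,"2-chloro-4-(2'-nitrilanilino)-6-isopropylamino-1,3,5-triazine",134,70,0.70,0.52
11,"2-chloro-4-(3'-nitrilanilino)-6-isopropylamino-1,3,5-triazine",134,108,0.70,0.34
12,"2-chloro-4-(4'-nitrilanilino)-6-isopropylamino-1,3,5-triazine",101,107,0.93,0.35
13,"2-chloro-4-(2'-triflourmethylanilino)-6-isopropylamino-1,3,5-triazine",91,81,1.02,0.46
14,"2-chloro-4-(3'-triflourmethylanilino)-6-isopropylamino-1,3,5-triazine",133,75,0.70,0.46
15,"2-chloro-4-(4'-triflourmethylanilino)-6-isopropylamino-1,3,5-triazine",92,129,1.02,0.49
16,"2-chloro-4-(3',4'-dimethoxyanilino)-6-ethylamino-1,3,5-triazine",5,10,18.6,3.68
17,"2-hydroxy-4-anilino-6-isopropylamino-1,3,5-triazine",0.4,0.2,232,186
18,"2-hydroxy-4-(3',4'-dimethoxyanilino)-6-isopropylamino-1,3,5-triazine",0.4,0.2,232,186
19,"2-chloro-4-anilino-6-amino-1,3,5-triazine",0.1,<0.1,500,>500
20,"2-chloro-4-(3',4'-dimethoxyanilino)-6-amino-1,3,5-triazine",<0.1,<0.1,>500,>500
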