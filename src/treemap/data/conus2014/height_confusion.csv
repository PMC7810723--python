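imputed,3,8,18,38,70
3,126839018,491213,9242,577,0
8,10257788,334363687,1414291,72269,288
18,4434215,1848028,2000161513,3368066,5831
38,471283,838750,72193,353795222,175244
70,32855,20755,1231,4892,2923530
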