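imputed,15,25,35,45,55,65,75,85,95
15,113259693,2637198,4108223,529979,194475,63431,43103,16190,4965
25,5017812,201658721,6422551,788100,355138,131744,62121,16986,4713
35,2524783,4130464,297997650,2590566,887885,421810,143835,56191,15817
45,565367,1312429,7681977,269346353,3154093,1437401,346507,89705,18245
55,140426,668783,1356709,2604891,276169764,2747460,742746,336838,66900
65,214322,366572,1160443,807754,2940943,291577963,1771381,671736,145536
75,38790,130397,448613,854545,1525144,1220510,709268338,1993144,730487
85,43800,115488,663493,485575,902553,573635,1144017,588746172,2918495
95,19730,93373,217297,184525,1225748,148633,386346,304505,14691240
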