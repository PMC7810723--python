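evg,spcd
613,202
613,122
613,108
613,93
613,19
613,73
613,117
613,242
615,122
615,202
615,15
615,81
615,116
615,137
615,20
615,103
618,108
618,93
618,19
618,746
618,101
618,113
618,18
618,94
625,65
625,106
625,69
625,66
625,814
625,322
625,133
625,68
630,746
630,747
630,375
630,371
630,95
630,741
630,313
630,742
636,202
636,263
636,242
636,98
636,352
636,11
636,17
636,231
648,802
648,833
648,837
648,832
648,806
648,812
648,835
648,404
660,316
660,531
660,621
660,832
660,833
660,951
660,762
660,611
668,462
668,731
668,95
668,313
668,543
668,544
668,931
668,972
682,318
682,371
682,375
682,241
682,261
682,531
682,97
682,12
693,97
693,12
693,95
693,316
693,318
693,371
693,241
693,261
697,131
697,110
697,111
697,121
697,611
697,693
697,827
697,694
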