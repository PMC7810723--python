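imputed,none,fire,insect_disease
none,2532706942,114511377,8522868
fire,17207086,30875524,191143
insect_disease,122784053,12746499,2056489
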