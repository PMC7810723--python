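source_evg,target_evg_or_DROP
692,693
705,668
649,DROP
730,DROP
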