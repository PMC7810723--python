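metric,count,denominator
cover_any_match_imputed,1257,2858
cover_any_match_target,1250,2858
height_any_match_imputed,2449,2858
height_any_match_target,2440,2858
species_top2_match_imputed,2192,2858
cover_weighted_within_10_imputed,1391,2858
cover_weighted_within_10_target,1393,2858
height_weighted_within_5m_imputed,2010,2858
height_weighted_within_5m_target,2006,2858
plots_used_in_imputation,62758,67141
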