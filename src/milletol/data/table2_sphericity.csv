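statistic,value
kmo_overall,0.819
bartlett_chi2,58.013
bartlett_df,28
bartlett_p,0.001
eigenvalue_1,3.929
eigenvalue_2,1.184
eigenvalue_3,1.025
variance_pct_1,49.111
variance_pct_2,14.804
variance_pct_3,12.807
cumulative_pct_3,76.722
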