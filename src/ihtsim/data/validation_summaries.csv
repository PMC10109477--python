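period,n_hist,mean_hist,se_hist,n_sim,mean_sim,se_sim
Night,13,2.31,0.82,30,2.07,0.27
Morning,13,49.54,2.5,30,46.63,0.94
Afternoon,13,11.77,1.4,30,11.33,0.63
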