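sample_id,clean_reads,full_length_reads,consensus_reads,mean_quality,fl_over_clean_pct,mapping_pct,gc_pct
A1,8053769,6399073,59413,9.6,79.5,75.80,43.31
A2,9792200,7421972,64491,9.5,75.8,65.47,42.60
A3,7924047,6420927,53684,9.6,81.0,71.77,43.25
C1,15766578,10163265,83749,9.3,64.5,55.15,42.10
C2,14440698,8618486,83397,9.2,59.7,58.97,42.27
C3,7607359,5972210,58999,9.7,78.5,71.28,43.87
RAC1,8664816,6699685,65629,9.4,81.8,68.84,43.75
RAC2,9305060,6531206,65041,9.3,83.2,69.63,43.13
RAC3,7226119,7262352,69989,9.4,83.3,72.54,44.10
NAC1,8191696,7041196,67755,9.4,81.3,71.07,43.80
NAC2,7852928,7397637,69475,9.5,79.5,82.66,43.87
NAC3,8716848,6072581,64014,9.4,84.0,81.77,43.83
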