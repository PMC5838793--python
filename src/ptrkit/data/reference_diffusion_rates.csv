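# Published diffusion-tube validation set: gravimetric vs PTR-ToF-MS release
# rates (ng/min, mean and SD over n = 3 replicates) for the study compounds,
# with the error percentages as printed in the original report.
compound,reagent,gravimetric_ng_min,gravimetric_sd,ptr_ng_min,ptr_sd,printed_error_pct
butanoic acid,hydronium,9061,291,8540,543,-5.7
pentanoic acid,hydronium,4261,75,4076,152,4.3
hexanoic acid,hydronium,3820,116,3870,135,-1.3
butanal,nitrosonium,39628,922,38112,2692,3.8
decanal,nitrosonium,3969,193,3649,175,8.0
phenol,hydronium,2603,108,2131,144,18.1
phenol,nitrosonium,2565,62,2365,112,7.7
phenol,dioxygenyl,2579,71,2434,144,5.6
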