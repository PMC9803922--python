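species,acclimation,fluid,mean_mM,sd_mM,n
river,FW,serum,0.0060,0.0012,4
river,SW,serum,0.057,0.035,6
tiger,BW,serum,0.0079,0.0017,4
tiger,SW,serum,0.024,0.010,4
river,FW,urine,0.020,0.019,7
river,SW,urine,19,8.3,6
tiger,SW,urine,14,4.5,5
river,SW,rectal_fluid,0.15,0.12,4
tiger,SW,rectal_fluid,0.04,0.02,4
river,SW,environment,0.45,0.02,3
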