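compound,dose_ug_cm2,duration_h,solvent,ph,observed_flux_ug_cm2_h,observed_flux_sd,observed_Q_ug_cm2,reference
buprenorphine,2656,72,0.1 M acetate buffer,4,0.08,0.02,5.54,Barret et al. 1994
diamorphine,53100,72,0.1 M acetate buffer,4,0.07,,2.59,Barret et al. 1993
phenobarbital,78,12,ethanol,,0.1,0.02,0.91,Bonina et al. 1993
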