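compound,gestational_age_w,postnatal_age_value,postnatal_age_unit,dose_ug_cm2,duration_h,solvent,ph,observed_flux_ug_cm2_h,reference
buprenorphine,38,1,d,2656,72,0.1 M acetate buffer,4,0.01,Barret et al. 1994
buprenorphine,40,7,h,2656,72,0.1 M acetate buffer,4,0.36,Barret et al. 1994
buprenorphine,37,1,d,2656,72,0.1 M acetate buffer,4,0.08,Barret et al. 1994
buprenorphine,37,1,d,2656,72,0.1 M acetate buffer,4,0.11,Barret et al. 1994
diamorphine,38,26,d,53100,72,0.1 M acetate buffer,4,0.23,Barret et al. 1993
diamorphine,40,7,d,53100,72,0.1 M acetate buffer,4,0.08,Barret et al. 1993
diamorphine,36,3,d,53100,72,0.1 M acetate buffer,4,0.18,Barret et al. 1993
phenobarbital,38,2,d,78,12,ethanol,,0.11,Bonina et al. 1993
phenobarbital,40,5,d,78,12,ethanol,,0.14,Bonina et al. 1993
phenobarbital,37,5,d,78,12,ethanol,,0.11,Bonina et al. 1993
phenobarbital,35,2,d,78,12,ethanol,,0.24,Bonina et al. 1993
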