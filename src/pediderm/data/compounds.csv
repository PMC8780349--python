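name,mw_g_mol,log_kow,pka,ionization_class,sol_water_mg_L,sol_vehicle_mg_mL,melting_point_c
buprenorphine,467.6,4,8.65,basic,16.8,,217
diamorphine,369.4,1.5,7.83,basic,600,,173
phenobarbital,232.2,1.47,7.3,acidic,1110,100,174
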