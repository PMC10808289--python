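plot_id,altitude_m,tmean_c,tmax_c,tmin_c,dtr_c,rain_mm_y,solar_mj_m2_d,vp_kpa,vpd_kpa,wind_m_s,swd_max_mm,cswd_max_mm,n_dry_months,dry_months
KDN1,117,26.40,29.52,23.57,5.95,3670,18.945,2.83,0.71,2.3,7.01,10.73,0,
KDN2,174,26.18,29.14,22.98,6.16,3858,18.833,2.75,0.67,2.3,5.85,9.49,0,
PTD2,509,24.15,27.49,20.99,6.50,3899,18.496,2.17,0.97,1.9,6.06,9.70,0,
PTD1,618,23.82,26.99,20.65,6.34,3911,18.330,2.00,0.98,1.9,6.06,9.70,0,
ENS1,1042,21.56,24.84,18.32,6.51,3130,17.910,2.00,0.58,2.2,17.58,23.71,0,
ENS2,1065,21.56,24.84,18.32,6.51,3130,17.910,2.00,0.58,2.2,17.58,23.71,0,
RLG,1668,19.65,23.40,15.82,7.58,2796,17.731,1.75,0.43,1.8,15.04,27.43,1,Feb
HKG,1804,17.05,20.67,13.48,7.19,2024,17.688,1.75,0.25,2.0,28.29,48.61,3,Feb;Mar;Jun
PTG,2080,15.56,19.14,11.98,7.15,1949,17.460,1.17,0.64,1.9,36.28,66.55,3,Feb;Mar;Jun
HNP,2132,14.75,18.32,11.34,6.98,2049,17.398,1.17,0.55,2.1,42.21,73.93,2,Feb;Mar
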