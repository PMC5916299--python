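animal_id,strategy,at_sea_fmr_wkg_nagy,at_sea_fmr_wkg_speakman,mean_depth_m,mean_duration_s,mean_ascent_rate_ms,mean_descent_rate_ms,mean_bout_duration_hr
C2,Mixed,5.30,3.29,54.5,119.3,1.18,1.11,1.3
C8,Mixed,8.00,5.98,93.3,185.0,1.50,1.63,1.5
C12,Mixed,8.84,6.97,130.5,226.2,1.44,1.53,1.9
C14,Mixed,6.72,5.35,39.0,142.1,1.15,1.32,2.0
C16,Mixed,7.85,6.01,143.2,225.8,1.49,1.53,1.2
C20,Mixed,6.49,4.95,42.1,132.3,1.24,1.43,1.4
C22,Mixed,8.27,6.44,92.2,173.3,1.45,1.44,1.7
WAF2001,Mixed,6.70,5.21,32.0,122.1,1.13,1.21,1.2
WAF2002,Mixed,5.58,3.93,74.1,202.3,1.17,1.33,1.6
WAF2010,Mixed,7.26,5.47,82.4,167.7,1.23,1.31,1.7
WAF2025,Mixed,7.18,5.20,41.9,157.2,1.07,1.06,1.3
C3,Deep,7.29,5.29,161.7,238.0,1.44,1.61,1.8
C18,Deep,6.56,4.75,188.9,255.5,1.45,1.59,2.5
WAF2007,Deep,6.15,4.51,203.0,265.2,1.54,1.63,3.3
WAF2018,Deep,7.10,5.25,105.2,169.6,1.02,1.00,1.1
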