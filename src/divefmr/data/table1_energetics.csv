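animal_id,island,mass_initial_kg,mass_final_kg,pup,pup_mass_kg,interval_days,time_at_sea_days,tbw_percent,influx_ml_kg_day,co2_nagy_ml_g_hr,co2_speakman_ml_g_hr,fmr_w_nagy,fmr_w_speakman,fmr_wkg_nagy,fmr_wkg_speakman
C2,SNI,85.4,81.2,Y,22.2,7.2,4.1,65.0,174,0.449,0.233,245.3,127.0,2.94,1.52
C3,SNI,78.0,75.4,Y,,8.1,4.2,64.7,154,0.763,0.545,383.7,274.2,5.00,3.58
C8,SNI,59.8,63.4,Y,13.0,9.0,6.6,66.6,172,0.997,0.743,402.5,300.4,6.53,4.88
C12,SNI,78.4,79.4,U,,17.1,11.0,47.5,129,1.045,0.836,540.6,432.6,6.85,5.48
C14,SNI,86.2,76.0,U,,11.9,8.4,64.0,83,0.774,0.628,411.5,334.1,5.07,4.12
C16,SNI,94.2,87.0,Y,,14.1,8.8,63.5,130,0.880,0.678,522.7,402.9,5.77,4.45
C18,SNI,86.0,84.8,Y,,11.1,7.3,65.1,139,0.713,0.510,399.1,285.6,4.67,3.34
C20,SNI,82.8,76.2,U,,10.1,4.8,62.1,77,0.544,0.420,283.4,219.0,3.56,2.75
C22,SNI,95.4,83.2,Y,8.3,11.2,7.3,63.0,127,0.969,0.763,567.4,446.7,6.35,5.00
WAF2001,SMI,84.5,72.0,Y,19.0,3.8,2.2,63.2,85,0.664,0.527,340.8,270.2,4.35,3.45
WAF2002,SMI,85.2,79.8,Y,13.0,9.9,7.1,62.9,142,0.606,0.415,327.7,224.3,3.97,2.72
WAF2007,SMI,81.8,80.2,Y,14.8,5.9,4.9,63.6,150,0.791,0.578,420.2,306.7,5.19,3.79
WAF2010,SMI,75.6,74.0,Y,16.6,4.8,2.8,64.0,124,0.756,0.571,370.6,279.9,4.95,3.74
WAF2018,SMI,86.9,79.6,Y,19.8,10.8,5.4,64.4,122,0.662,0.486,361.5,265.3,4.34,3.18
WAF2025,SMI,78.9,77.9,Y,17.2,8.1,5.8,63.4,170,0.855,0.614,439.5,315.7,5.61,4.03
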