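model,source_pressure_mpa,tissue,terminal,propagation_time_us,voltage_mv,pressure_mpa,intensity_w_cm2,attenuation_db
cervical,0.25,Initial value at epidermis surface,T1:A+,0,17.5,0.25,1.86,0
cervical,0.25,Left Recurrent Laryngeal Nerve,T7:B+,708.52,12.84,0.18,0.96,-2.69
cervical,0.25,Cardiac Plexus,T9:B+,370.97,9.18,0.13,0.49,-5.60
cervical,0.25,Hepatic Plexus,T16:B+,523.09,4.64,0.07,0.13,-11.54
cervical,0.25,Gastric Plexus,T18:B+,492.40,4.45,0.06,0.12,-11.88
cervical,0.25,Splenic Nerve,T14:B+,504.67,4.43,0.06,0.11,-11.93
site_focused,0.25,Initial value at epidermis surface,T1:A+,0,17.5,0.25,1.86,0
site_focused,0.25,Splenic Nerve,T8:B+,57.55,19.39,0.28,2.19,0.89
cervical,0.83,Initial value at epidermis surface,T1:A+,0,58.1,0.83,20.53,0
cervical,0.83,Left Recurrent Laryngeal Nerve,T7:B+,708.51,40.37,0.58,9.49,-3.16
cervical,0.83,Cardiac Plexus,T9:B+,370.96,26.96,0.39,4.23,-6.67
cervical,0.83,Hepatic Plexus,T16:B+,523.08,13.48,0.19,1.06,-12.69
cervical,0.83,Gastric Plexus,T18:B+,492.45,13.18,0.19,1.01,-12.89
cervical,0.83,Splenic Nerve,T14:B+,504.72,13.18,0.19,1.01,-12.89
site_focused,0.83,Initial value at epidermis surface,T1:A+,0,58.1,0.83,20.53,0
site_focused,0.83,Splenic Nerve,T8:B+,57.53,60.66,0.87,21.43,0.37
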