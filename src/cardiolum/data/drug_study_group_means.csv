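experiment,group,metric,mean,sd,n
propranolol,control,fs_major,0.28,0.03,20
propranolol,control,fs_minor,0.33,0.06,20
propranolol,control,fac,0.39,0.05,20
propranolol,control,edv_pl,420.9,89.6,20
propranolol,control,esv_pl,137.5,39.7,20
propranolol,control,sv_pl,283.3,66.0,20
propranolol,control,hr_bpm,251,20,20
propranolol,control,co_nl_min,72.0,21.3,20
propranolol,control,ef,0.67,0.07,20
propranolol,control,av_hr_ratio,1.00,0.00,20
propranolol,control,avg_ca,56.8,24.5,6
propranolol,treated,fs_major,0.22,0.03,20
propranolol,treated,fs_minor,0.27,0.06,20
propranolol,treated,fac,0.34,0.05,20
propranolol,treated,edv_pl,420.7,94.7,20
propranolol,treated,esv_pl,177.2,45.2,20
propranolol,treated,sv_pl,243.5,71.9,20
propranolol,treated,hr_bpm,212,15,20
propranolol,treated,co_nl_min,51.8,15.8,20
propranolol,treated,ef,0.58,0.08,20
propranolol,treated,av_hr_ratio,1.00,0.00,20
propranolol,treated,avg_ca,26.1,5.7,6
terfenadine,control,fs_major,0.36,0.04,18
terfenadine,control,fs_minor,0.37,0.05,18
terfenadine,control,fac,0.39,0.04,18
terfenadine,control,edv_pl,422.1,115.3,18
terfenadine,control,esv_pl,109.3,39.6,18
terfenadine,control,sv_pl,312.8,84.2,18
terfenadine,control,hr_bpm,229.9,19.1,18
terfenadine,control,co_nl_min,72.4,21.2,18
terfenadine,control,ef,0.74,0.05,18
terfenadine,control,av_hr_ratio,1.00,0.00,18
terfenadine,control,avg_ca,58.9,17.3,10
terfenadine,control,cat_amp,61.0,28.3,16
terfenadine,control,ca_syst,71.6,36.0,16
terfenadine,control,ca_diast,10.6,12.0,16
terfenadine,treated,fs_major,0.27,0.06,19
terfenadine,treated,fs_minor,0.46,0.05,19
terfenadine,treated,fac,0.47,0.08,19
terfenadine,treated,edv_pl,518.7,127.6,19
terfenadine,treated,esv_pl,108.8,31.7,19
terfenadine,treated,sv_pl,409.9,105.7,19
terfenadine,treated,hr_bpm,94.1,12.9,19
terfenadine,treated,co_nl_min,37.7,8.7,19
terfenadine,treated,ef,0.78,0.06,19
terfenadine,treated,av_hr_ratio,0.51,0.11,19
terfenadine,treated,avg_ca,28.4,11.8,9
terfenadine,treated,cat_amp,121.5,21.4,9
terfenadine,treated,ca_syst,125.1,21.1,9
terfenadine,treated,ca_diast,4.0,2.4,9
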