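age_lo,age_hi,sex,index,mean,sd,source
20,29,M,rmssd_ms,47.0,14.0,synthetic-default
20,29,M,hrt_ts,7.5,2.5,synthetic-default
20,29,M,brs,19.47,7.3,synthetic-default
20,29,M,lf_power_ms2,600.0,250.0,synthetic-default
20,29,M,lf_hf,2.0,1.0,synthetic-default
20,29,F,rmssd_ms,47.0,14.0,synthetic-default
20,29,F,hrt_ts,7.5,2.5,synthetic-default
20,29,F,brs,19.47,7.3,synthetic-default
20,29,F,lf_power_ms2,600.0,250.0,synthetic-default
20,29,F,lf_hf,2.0,1.0,synthetic-default
30,39,M,rmssd_ms,47.0,14.0,synthetic-default
30,39,M,hrt_ts,7.5,2.5,synthetic-default
30,39,M,brs,19.47,7.3,synthetic-default
30,39,M,lf_power_ms2,600.0,250.0,synthetic-default
30,39,M,lf_hf,2.0,1.0,synthetic-default
30,39,F,rmssd_ms,47.0,14.0,synthetic-default
30,39,F,hrt_ts,7.5,2.5,synthetic-default
30,39,F,brs,19.47,7.3,synthetic-default
30,39,F,lf_power_ms2,600.0,250.0,synthetic-default
30,39,F,lf_hf,2.0,1.0,synthetic-default
40,49,M,rmssd_ms,47.0,14.0,synthetic-default
40,49,M,hrt_ts,7.5,2.5,synthetic-default
40,49,M,brs,19.47,7.3,synthetic-default
40,49,M,lf_power_ms2,600.0,250.0,synthetic-default
40,49,M,lf_hf,2.0,1.0,synthetic-default
40,49,F,rmssd_ms,47.0,14.0,synthetic-default
40,49,F,hrt_ts,7.5,2.5,synthetic-default
40,49,F,brs,19.47,7.3,synthetic-default
40,49,F,lf_power_ms2,600.0,250.0,synthetic-default
40,49,F,lf_hf,2.0,1.0,synthetic-default
50,59,M,rmssd_ms,47.0,14.0,synthetic-default
50,59,M,hrt_ts,7.5,2.5,synthetic-default
50,59,M,brs,19.47,7.3,synthetic-default
50,59,M,lf_power_ms2,600.0,250.0,synthetic-default
50,59,M,lf_hf,2.0,1.0,synthetic-default
50,59,F,rmssd_ms,47.0,14.0,synthetic-default
50,59,F,hrt_ts,7.5,2.5,synthetic-default
50,59,F,brs,19.47,7.3,synthetic-default
50,59,F,lf_power_ms2,600.0,250.0,synthetic-default
50,59,F,lf_hf,2.0,1.0,synthetic-default
60,69,M,rmssd_ms,47.0,14.0,synthetic-default
60,69,M,hrt_ts,7.5,2.5,synthetic-default
60,69,M,brs,19.47,7.3,synthetic-default
60,69,M,lf_power_ms2,600.0,250.0,synthetic-default
60,69,M,lf_hf,2.0,1.0,synthetic-default
60,69,F,rmssd_ms,47.0,14.0,synthetic-default
60,69,F,hrt_ts,7.5,2.5,synthetic-default
60,69,F,brs,19.47,7.3,synthetic-default
60,69,F,lf_power_ms2,600.0,250.0,synthetic-default
60,69,F,lf_hf,2.0,1.0,synthetic-default
70,79,M,rmssd_ms,47.0,14.0,synthetic-default
70,79,M,hrt_ts,7.5,2.5,synthetic-default
70,79,M,brs,19.47,7.3,synthetic-default
70,79,M,lf_power_ms2,600.0,250.0,synthetic-default
70,79,M,lf_hf,2.0,1.0,synthetic-default
70,79,F,rmssd_ms,47.0,14.0,synthetic-default
70,79,F,hrt_ts,7.5,2.5,synthetic-default
70,79,F,brs,19.47,7.3,synthetic-default
70,79,F,lf_power_ms2,600.0,250.0,synthetic-default
70,79,F,lf_hf,2.0,1.0,synthetic-default
80,89,M,rmssd_ms,47.0,14.0,synthetic-default
80,89,M,hrt_ts,7.5,2.5,synthetic-default
80,89,M,brs,19.47,7.3,synthetic-default
80,89,M,lf_power_ms2,600.0,250.0,synthetic-default
80,89,M,lf_hf,2.0,1.0,synthetic-default
80,89,F,rmssd_ms,47.0,14.0,synthetic-default
80,89,F,hrt_ts,7.5,2.5,synthetic-default
80,89,F,brs,19.47,7.3,synthetic-default
80,89,F,lf_power_ms2,600.0,250.0,synthetic-default
80,89,F,lf_hf,2.0,1.0,synthetic-default
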