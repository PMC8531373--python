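sample_id,group_tag,M1_n,M1_mean,M1_sd,M8_n,M8_mean,M8_sd,M9_n,M9_mean,M9_sd,M10_n,M10_mean,M10_sd,M17_n,M17_mean,M17_sd,M43_n,M43_mean,M43_sd,M45_n,M45_mean,M45_sd,M46_n,M46_mean,M46_sd,M48_n,M48_mean,M48_sd,M51_n,M51_mean,M51_sd,M52_n,M52_mean,M52_sd,M54_n,M54_mean,M54_sd,M55_n,M55_mean,M55_sd
Huiyaotian,focal,4,195.8,3.5,2,135.5,7.8,4,96.5,5.8,2,114.5,3.5,2,145.0,14.1,4,110.3,7.8,3,140.7,1.2,3,105.3,3.0,5,66.5,4.6,3,42.3,3.4,4,34.8,3.4,4,27.7,1.6,4,51.2,1.5
Liyupo,focal,3,184.3,8.4,3,133.3,4.2,3,98.8,3.9,3,112.3,4.9,3,132.3,5.5,3,109.9,3.6,2,131.6,7.6,3,103.6,4.4,2,62.5,2.2,2,41.2,1.1,2,34.4,0.8,3,27.4,1.4,2,46.5,2.1
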