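specimen_id,site,sex,M1,M8,M9,M10,M17,M43,M45,M46,M48,M51,M52,M54,M55
Yahuai,Yahuai Cave,F,190,147,109,130,143,115,152,98,62,(41),35,25,48
04HCH3-M1,Hang Cho,F,192,138,100,112,135,113,128,95,61,42,31,26,47
84MDD-M1,Mai Da Dieu,F,181,126,89,100,(130),112,120,103,58,38,33,27,43
14BD1-M4,Bau Du,F,172,133,93,110,133,108,(134),110,59,41,31,26,44
C5,Xiaoma,F,162,128,87,102,(132),96,(138),(104),59,38,31,26,43
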