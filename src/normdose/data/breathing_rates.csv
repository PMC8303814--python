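age_group,unit,value,comment
one_year_old,m3_per_day,5.1,
one_year_old,m3_per_hour,0.2125,
one_year_old,g_per_hour,260,
ten_year_old,m3_per_day,15.2,
ten_year_old,m3_per_hour,0.63,published rounding disagrees with 15.2/24 = 0.6333 by 0.53%
ten_year_old,g_per_hour,775,
adult,m3_per_day,22.2,
adult,m3_per_hour,0.925,
adult,g_per_hour,1133.13,source prints 1331.13; digit transposition of 0.925 m3/h x 1225 g/m3 = 1133.13
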