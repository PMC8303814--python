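nuclide,f1,age_group,value,unit,comment
U-238,0.02,one_year_old,1.2e-7,Sv/Bq,
U-238,0.02,ten_year_old,6.8e-8,Sv/Bq,
U-238,0.02,adult,4.5e-8,Sv/Bq,
Th-232,0.0005,one_year_old,4.5e-7,Sv/Bq,
Th-232,0.0005,ten_year_old,2.9e-7,Sv/Bq,
Th-232,0.0005,adult,2.3e-7,Sv/Bq,
K-40,1.0,one_year_old,4.2e-8,Sv/Bq,
K-40,1.0,ten_year_old,1.3e-8,Sv/Bq,
K-40,1.0,adult,6.2e-9,Sv/Bq,
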