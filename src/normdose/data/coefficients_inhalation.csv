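nuclide,absorption_type,f1,age_group,value,unit,comment
U-238,F,0.02,one_year_old,1.3e-6,Sv/Bq,
U-238,F,0.02,ten_year_old,7.3e-4,Sv/Bq,magnitude anomalous vs neighbouring age columns; carried as published
U-238,F,0.02,adult,5.0e-7,Sv/Bq,
U-238,M,0.02,one_year_old,9.4e-6,Sv/Bq,
U-238,M,0.02,ten_year_old,4.0e-4,Sv/Bq,magnitude anomalous vs neighbouring age columns; carried as published
U-238,M,0.02,adult,2.9e-6,Sv/Bq,
U-238,S,0.002,one_year_old,2.5e-6,Sv/Bq,
U-238,S,0.002,ten_year_old,1.0e-4,Sv/Bq,magnitude anomalous vs neighbouring age columns; carried as published
U-238,S,0.002,adult,8.0e-6,Sv/Bq,
Th-232,F,0.0005,one_year_old,2.2e-6,Sv/Bq,
Th-232,F,0.0005,ten_year_old,1.3e-4,Sv/Bq,
Th-232,F,0.0005,adult,1.1e-4,Sv/Bq,
Th-232,M,0.0005,one_year_old,8.1e-5,Sv/Bq,
Th-232,M,0.0005,ten_year_old,5.0e-5,Sv/Bq,
Th-232,M,0.0005,adult,4.5e-5,Sv/Bq,
Th-232,S,0.0005,one_year_old,5.0e-5,Sv/Bq,
Th-232,S,0.0005,ten_year_old,2.6e-5,Sv/Bq,
Th-232,S,0.0005,adult,2.5e-5,Sv/Bq,
K-40,F,1.0,one_year_old,1.7e-8,Sv/Bq,
K-40,F,1.0,ten_year_old,4.5e-9,Sv/Bq,
K-40,F,1.0,adult,2.1e-9,Sv/Bq,
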