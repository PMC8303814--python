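nuclide,age_group,value,unit,comment
U-238,one_year_old,1.48e-16,Sv/h per Bq/g,
U-238,ten_year_old,1.15e-16,Sv/h per Bq/g,
U-238,adult,9.44e-17,Sv/h per Bq/g,
Th-232,one_year_old,5.06e-16,Sv/h per Bq/g,
Th-232,ten_year_old,4.02e-16,Sv/h per Bq/g,
Th-232,adult,3.37e-16,Sv/h per Bq/g,
K-40,one_year_old,4.39e-13,Sv/h per Bq/g,
K-40,ten_year_old,3.79e-13,Sv/h per Bq/g,
K-40,adult,3.46e-13,Sv/h per Bq/g,
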