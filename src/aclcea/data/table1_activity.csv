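study,arm,n,class_I,class_II,class_III,class_IV,class_V,age_years,followup_months
Finke_2001,operative,46,2,12,12,20,0,34,132
Diekstall_1999,operative,60,5,6,6,11,32,27.9,51
Kessler_2008,operative,60,5,6,6,11,32,30.7,140
Seitz_1994,operative,63,0,0,7,56,0,25,102
Finke_2001,conservative,25,11,6.5,6.5,1,0,32,140
Diekstall_1999,conservative,49,7,7.5,7.5,20,7,23.8,53
Kessler_2008,conservative,60,5,6,6,11,32,30.7,140
Seitz_1994,conservative,21,0,3,12,6,0,28,102
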