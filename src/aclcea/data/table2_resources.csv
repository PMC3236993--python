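profile,name,quantity,unit_cost,line_cost
surgical,Outpatient visit (15 min),5,144,718
surgical,X-ray (knee 3 views),1,128,128
surgical,MRI,1,419,419
surgical,In-hospital stay and OR,4.8,7391,7391
surgical,Low molecular heparin (16 days 1/day),16,9,150
surgical,Analgesic agents (16 days 3/day),16,3,157
surgical,Physiotherapy units,14,42,672
surgical,Orthesis,1,291,291
conservative,Outpatient visit (15 min),3,144,431
conservative,X-ray (knee 3 views),1,128,128
conservative,MRI,1,419,419
conservative,Low molecular heparin (21 days 1/day),21,9,197
conservative,Analgesic agents (21 days 3/day),21,3,205
conservative,Physiotherapy units,18,42,864
conservative,Orthesis,1,291,291
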