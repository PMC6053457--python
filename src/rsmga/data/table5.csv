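step,protein_mg,activity_u,specific_activity_printed,yield_pct_printed,fold_printed
Culture supernatant,1550,1865,1.20,100,1
Ammonium sulphate,550,1470,2.67,78.82,2.22
DEAE cellulose,220,1150,5.22,61.62,4.35
Sephadex G-100,80,990,12.37,53.08,10.31
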