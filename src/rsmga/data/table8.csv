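substrate,relative_activity_pct
Cholesterol,100
beta-Cholestanol,96
beta-Sitosterol,88
beta-Stigmasterol,68
Pregnenolone,46
Dehydroepiandrosterone,30
Epiandrosterone,15
Ergosterol,12
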