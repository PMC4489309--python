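symbol,name,mass_shift,residues
ox,Oxidation,15.994915,M
cmm,Carbamidomethyl,57.021464,C
ace-,Acetyl,42.010565,n-term
deam,Deamidated,0.984016,NQ
phos,Phospho,79.966331,STY
-am,Amidated,-0.984016,c-term
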