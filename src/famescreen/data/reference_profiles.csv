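# FAME composition of four microalgal isolates, mass percent of total
# lipid, from a published GC-MS screening of tropical-lake microalgae
# (two Micractinium conductrix strains, Choricystis parasitica,
# Monoraphidium sp.). Empty cells mean "not detected".
shorthand,fame_name,G4-3,G4-9,P2-15,P5-4
C14,Methyl myristate,0.45,0.33,4.29,0.43
C15,Methyl pentadecanoate,0.47,,,0.65
C16,Methyl palmitate,4.22,15.34,29.11,9.18
C16:1n-7,Methyl palmitoleate,3.98,2.12,1.55,3.38
C16:2n-6,"Methyl 7,10-hexadecadienoate",3.89,7.23,0.78,2.39
C16:3n-3,"Methyl 7,10,13-hexadecatrienoate",3.17,11.07,,0.73
C16:3n-6,"Methyl 4,7,10-hexadecatrienoate",0.78,,,3.45
C17,Methyl margarate,,,,0.37
C18,Methyl stearate,,,0.98,1.21
C18:1n-4,Methyl 14-octadecenoate,,1.77,,0.61
C18:1n-7,Methyl 11-octadecenoate,,,1.37,
C18:2n-6,Methyl linoleate,20.24,21.65,4.95,15.55
C18:3n-3,Methyl α-linolenate,14.82,23.95,26.83,32.00
C18:3n-6,Methyl γ-linolenate,1.04,,1.46,0.87
C20,Methyl arachidate,,,,1.04
C20:1n-9,Methyl 11-eicosenoate,,,0.94,
C20:4n-3,"Methyl 5,11,14,17-eicosatetraenoate",10.80,,,10.15
C20:5n-3,Methyl eicosapentaenoate,1.58,,4.18,3.25
C22,Methyl behenate,,,,0.33
C24,Methyl lignocerate,0.95,,3.88,0.45
C24:1n-9,Methyl 15-tetracosenoate,,,0.35,
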