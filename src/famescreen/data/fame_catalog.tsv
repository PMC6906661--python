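# Shorthand -> systematic methyl-ester (FAME) name.
# Covers the 21 fatty acids reported in a published GC-MS screening of
# four tropical-lake microalgal isolates, the profiles packaged as
# fixtures alongside this catalog.
shorthand	fame_name
C14	Methyl myristate
C15	Methyl pentadecanoate
C16	Methyl palmitate
C16:1n-7	Methyl palmitoleate
C16:2n-6	Methyl 7,10-hexadecadienoate
C16:3n-3	Methyl 7,10,13-hexadecatrienoate
C16:3n-6	Methyl 4,7,10-hexadecatrienoate
C17	Methyl margarate
C18	Methyl stearate
C18:1n-4	Methyl 14-octadecenoate
C18:1n-7	Methyl 11-octadecenoate
C18:2n-6	Methyl linoleate
C18:3n-3	Methyl α-linolenate
C18:3n-6	Methyl γ-linolenate
C20	Methyl arachidate
C20:1n-9	Methyl 11-eicosenoate
C20:4n-3	Methyl 5,11,14,17-eicosatetraenoate
C20:5n-3	Methyl eicosapentaenoate
C22	Methyl behenate
C24	Methyl lignocerate
C24:1n-9	Methyl 15-tetracosenoate
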