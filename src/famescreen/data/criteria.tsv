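# Default biodiesel-quality criteria. ASTM_D6751 = US standard,
# EN_14214 = European standard, paper_stated = range quoted alongside
# the standards in the source study without an explicit attribution.
# Empty cell = unbounded on that side; bounds are inclusive.
property_name	lower	upper	source
ADU	0.6	1.6	paper_stated
Vis	1.9	6.0	ASTM_D6751
SG	0.85	0.90	ASTM_D6751
CN	47		ASTM_D6751
IV		120	EN_14214
HHV	38	41	paper_stated
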