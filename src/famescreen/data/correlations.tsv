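# Default linear-in-ADU fuel-property correlation set:
# property = slope * ADU + intercept, printed to output_decimals.
property_name	slope	intercept	units	output_decimals
Vis	-0.6316	5.2065	mm^2 s^-1	2
SG	0.0055	0.8726	kg L^-1	3
CN	-6.6684	62.876		1
IV	74.373	12.71	g I2/100 g	2
HHV	1.7601	38.534	MJ kg^-1	1
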