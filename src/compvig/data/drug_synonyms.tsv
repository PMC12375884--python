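# synonym	canonical	class
pegcetacoplan	pegcetacoplan	C3
empaveli	pegcetacoplan	C3
aspaveli	pegcetacoplan	C3
apl-2	pegcetacoplan	C3
crovalimab	crovalimab	C5
piasky	crovalimab	C5
crovalimab-akkz	crovalimab	C5
eculizumab	eculizumab	C5
soliris	eculizumab	C5
pozelimab	pozelimab	C5
veopoz	pozelimab	C5
pozelimab-bbfg	pozelimab	C5
ravulizumab	ravulizumab	C5
ultomiris	ravulizumab	C5
ravulizumab-cwvz	ravulizumab	C5
iptacopan	iptacopan	FactorB
fabhalta	iptacopan	FactorB
iptacopan hydrochloride	iptacopan	FactorB
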