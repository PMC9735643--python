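variety	AK	BV	Bu	CJ	CBD1	CBD2	MB	Mot	SDA	THC1
AK	0	0.0388	0.0444	0.0463	0.0575	0.0575	0.0349	0.0407	0.0538	0.0423
BV	0.0388	0	0.052	0.0475	0.0697	0.0695	0.0514	0.0125	0.0556	0.0573
Bu	0.0444	0.052	0	0.0472	0.0589	0.0573	0.0425	0.0495	0.057	0.0506
CJ	0.0463	0.0475	0.0472	0	0.0664	0.0662	0.0478	0.0503	0.0572	0.0529
CBD1	0.0575	0.0697	0.0589	0.0664	0	0.0095	0.0599	0.0689	0.0665	0.06
CBD2	0.0575	0.0695	0.0573	0.0662	0.0095	0	0.0597	0.0673	0.066	0.0594
MB	0.0349	0.0514	0.0425	0.0478	0.0599	0.0597	0	0.0536	0.0552	0.0455
Mot	0.0407	0.0125	0.0495	0.0503	0.0689	0.0673	0.0536	0	0.0531	0.0538
SDA	0.0538	0.0556	0.057	0.0572	0.0665	0.066	0.0552	0.0531	0	0.0512
THC1	0.0423	0.0573	0.0506	0.0529	0.06	0.0594	0.0455	0.0538	0.0512	0
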