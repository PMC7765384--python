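alias	canonical
B2GP1	APOH
B2GPI	APOH
GP Ia	ITGA2
GPIa	ITGA2
GP IIIa	ITGB3
GPIIIa	ITGB3
ZPI	SERPINA10
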