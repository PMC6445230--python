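# npsid neutral-loss table v1
# columns: name,formula,diagnostic_of,radical
name,formula,diagnostic_of,radical
water,H2O,hydroxyl or protonated alcohol,0
ammonia,NH3,primary amine,0
methylamine,CH5N,N-methyl amine,0
carbon monoxide,CO,carbonyl or phenol,0
hydrogen cyanide,HCN,nitrile or N-heteroaromatic,0
methyl radical,CH3,methyl substituent (radical loss),1
ethylene,C2H4,ethyl chain or retro-ene,0
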