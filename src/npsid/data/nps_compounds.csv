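# npsid compound table v1 — curated NPS and common drugs of abuse
# columns: name,synonyms (| separated),formula,class
name,synonyms,formula,class
AMT,alpha-methyltryptamine|3-(2-aminopropyl)indole,C11H14N2,tryptamine
5-IT,5-(2-aminopropyl)indole,C11H14N2,tryptamine
AET,alpha-ethyltryptamine,C12H16N2,tryptamine
DMT,N.N-dimethyltryptamine,C12H16N2,tryptamine
DET,N.N-diethyltryptamine,C14H20N2,tryptamine
DiPT,N.N-diisopropyltryptamine,C16H24N2,tryptamine
5-MeO-DMT,5-methoxy-DMT,C13H18N2O,tryptamine
psilocin,4-HO-DMT,C12H16N2O,tryptamine
4-HO-MET,metocin,C13H18N2O,tryptamine
4-AcO-DMT,psilacetin,C14H18N2O2,tryptamine
5-MAPB,1-(benzofuran-5-yl)-N-methylpropan-2-amine,C12H15NO,benzofuran
6-MAPB,1-(benzofuran-6-yl)-N-methylpropan-2-amine,C12H15NO,benzofuran
5-APB,5-(2-aminopropyl)benzofuran,C11H13NO,benzofuran
6-APB,6-(2-aminopropyl)benzofuran,C11H13NO,benzofuran
5-EAPB,1-(benzofuran-5-yl)-N-ethylpropan-2-amine,C13H17NO,benzofuran
amphetamine,speed,C9H13N,phenethylamine
methamphetamine,metamfetamine,C10H15N,phenethylamine
4-FA,4-fluoroamphetamine,C9H12FN,phenethylamine
MDMA,3.4-methylenedioxy-methamphetamine|ecstasy,C11H15NO2,phenethylamine
MDA,3.4-methylenedioxyamphetamine,C10H13NO2,phenethylamine
MDEA,3.4-methylenedioxy-N-ethylamphetamine,C12H17NO2,phenethylamine
PMA,para-methoxyamphetamine,C10H15NO,phenethylamine
PMMA,para-methoxymethamphetamine,C11H17NO,phenethylamine
2C-B,4-bromo-2.5-dimethoxyphenethylamine,C10H14BrNO2,phenethylamine
2C-I,4-iodo-2.5-dimethoxyphenethylamine,C10H14INO2,phenethylamine
2C-E,4-ethyl-2.5-dimethoxyphenethylamine,C12H19NO2,phenethylamine
mescaline,3.4.5-trimethoxyphenethylamine,C11H17NO3,phenethylamine
bk-2C-B,2-amino-1-(4-bromo-2.5-dimethoxyphenyl)ethan-1-one,C10H12BrNO3,cathinone
cathinone,norephedrone,C9H11NO,cathinone
methcathinone,ephedrone,C10H13NO,cathinone
mephedrone,4-MMC|4-methylmethcathinone,C11H15NO,cathinone
3-MMC,3-methylmethcathinone,C11H15NO,cathinone
buphedrone,alpha-methylamino-butyrophenone,C11H15NO,cathinone
ethcathinone,N-ethylcathinone,C11H15NO,cathinone
4-MEC,4-methylethcathinone,C12H17NO,cathinone
pentedrone,alpha-methylaminovalerophenone,C12H17NO,cathinone
4-CMC,clephedrone|4-chloromethcathinone,C10H12ClNO,cathinone
4-CEC,4-chloroethcathinone,C11H14ClNO,cathinone
methylone,bk-MDMA,C11H13NO3,cathinone
butylone,bk-MBDB,C12H15NO3,cathinone
ethylone,bk-MDEA,C12H15NO3,cathinone
pentylone,bk-MBDP,C13H17NO3,cathinone
MDPV,methylenedioxypyrovalerone,C16H21NO3,cathinone
alpha-PVP,flakka,C15H21NO,cathinone
BZP,1-benzylpiperazine,C11H16N2,piperazine
mCPP,1-(3-chlorophenyl)piperazine,C10H13ClN2,piperazine
ketamine,special K,C13H16ClNO,arylcyclohexylamine
methoxetamine,MXE,C15H21NO2,arylcyclohexylamine
methylphenidate,ritalin,C14H19NO2,phenidate
caffeine,1.3.7-trimethylxanthine,C8H10N4O2,xanthine
cocaine,benzoylmethylecgonine,C17H21NO4,tropane
morphine,-,C17H19NO3,opioid
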