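descriptor,importance,relative_importance
AATSC7i,0.0403,1.0000
VR2_Dzp,0.0138,0.3295
ATSC4v,0.0089,0.2077
VE2_DzZ,0.0302,0.7437
mindssC,0.0135,0.3227
BCUTc-1l,0.0088,0.2031
ATSC4c,0.0293,0.7231
ATSC8p,0.0135,0.3225
ATSC1e,0.0087,0.2005
VE2_Dzp,0.0292,0.7198
AATS5s,0.0133,0.3167
minHBa,0.0087,0.2004
GATS3e,0.0282,0.6945
ALogp2,0.0131,0.3136
ATSC6e,0.0086,0.1990
GATS3c,0.0273,0.6704
ATSC2e,0.0128,0.3053
AATS7i,0.0086,0.1982
GATS1m,0.0247,0.6056
AATSC8i,0.0128,0.3051
TopoPSA,0.0084,0.1941
VE3_Dzm,0.0237,0.5803
VE2_Dze,0.0125,0.2974
VC-4,0.0082,0.1888
ASP-5,0.0224,0.5467
VE2_Dt,0.0123,0.2929
AATS7s,0.0080,0.1828
GATS4c,0.0216,0.5275
ATSC4s,0.0121,0.2878
MATS2s,0.0078,0.1778
ATSC2c,0.0208,0.5077
AATSC3m,0.0114,0.2707
WTPT-5,0.0070,0.1596
JGI7,0.0206,0.5024
topoShape,0.0111,0.2629
VR2_DzZ,0.0065,0.1446
ASP-7,0.0198,0.4810
JGI8,0.0110,0.2597
AATSC7c,0.0059,0.1298
GATS2m,0.0197,0.4788
JGI3,0.0110,0.2585
JGI2,0.0056,0.1240
MDEC-13,0.0192,0.4669
AATS8s,0.0107,0.2513
nAtomLC,0.0049,0.1045
GATS2s,0.0191,0.4651
AATSC0i,0.0105,0.2467
SC-5,0.0048,0.1039
ATSC5s,0.0191,0.4642
GATS3s,0.0103,0.2413
apol,0.0047,0.0997
AATS1i,0.0189,0.4580
MATS2m,0.0101,0.2365
minsssCH,0.0034,0.0664
ATSC6p,0.0172,0.4159
VE2_Dzv,0.0099,0.2320
JGI5,0.0030,0.0585
JGI6,0.0172,0.4157
SpMin8_Bhi,0.0099,0.2308
minsCl,0.0022,0.0371
SpMin6_Bhi,0.0170,0.4111
GATS7i,0.0098,0.2290
SC-4,0.0021,0.0354
ATSC8e,0.0168,0.4061
MDEC-11,0.0098,0.2285
nAtomLAC,0.0021,0.0340
MLFER_BO,0.0167,0.4043
AATSC6m,0.0097,0.2262
ETA_dAlpha_B,0.0015,0.0187
AATSC7s,0.0165,0.3998
ATSC5p,0.0096,0.2254
MDEC-24,0.0012,0.0109
MDEO-22,0.0158,0.3802
VE2_Dzs,0.0094,0.2201
minHCsatu,0.0011,0.0106
SpMin7_Bhi,0.0147,0.3523
ASP-6,0.0090,0.2102
minwHBd,0.0007,0.0000
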