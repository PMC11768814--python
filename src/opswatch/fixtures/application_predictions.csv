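name,prediction
(E)-Mevinphos,Banned
(Z)-Mevinphos,Banned
"2,5-dichloro-alpha-(chloromethylene)benzyl diethyl phosphate",Banned
"2,5-dichloro-alpha-(dichloromethylene)benzyl diethyl phosphate",Unrestricted
Acetoxon,Banned
Akton,Unrestricted
"alpha,alpha-Dithiol bis(O,O-dimethyl phosphorodithioate)toluene",Unrestricted
Amidithion,Unrestricted
Aminofenitrothion,Unrestricted
Amiprofos-methyl,Unrestricted
Amiton oxalate,Unrestricted
Amiton,Unrestricted
Aspon,Banned
Athidathion,Unrestricted
Azethion,Unrestricted
Azinphos-methyl oxygen analog,Banned
Azothoate,Unrestricted
Bensulide Oxon (degradate of bensulide),Banned
Bensulide,Banned
Bomyl,Banned
Buminafos,Unrestricted
Butamifos,Unrestricted
Butathiofos,Unrestricted
Butonate,Unrestricted
Calvinphos,Unrestricted
Carbophenothion-methyl,Banned
Chlorfenvinphos alpha,Banned
Chlorfenvinphos-methyl,Unrestricted
Chlorphoxim,Banned
Chlorprazophos,Unrestricted
Chlorpyifos oxygen analog,Banned
Chlorthion,Unrestricted
Chlorthiophos I,Unrestricted
Chlorthiophos II,Unrestricted
Chlorthiophos III,Unrestricted
cis-Azodrin,Unrestricted
cis-Methocrotophos,Banned
Coumaphos oxon (metabolite of coumaphos),Unrestricted
Coumithioate,Banned
Crotoxyphos,Banned
Crufomate,Restricted
Cyanofenphos,Unrestricted
Cyanthoate,Banned
Cythioate,Unrestricted
Demephion-O,Restricted
Demephion-S,Restricted
Demeton-O-methyl,Banned
Demeton-O,Unrestricted
Demeton-S sulfone,Banned
Demeton,Banned
Dequest 2010 phosphonate,Unrestricted
Desbromoleptophos,Unrestricted
Desmethyl fenitrothion (metabolite of fenitrothion),Banned
Desmethyl malathion (metabolite of malathion),Banned
"Phosphorodithioic acid, O-methyl ester, S-ester with 2-mercapto-N-methylacetamide, S-potassium salt",Banned
Desmethylfenitrothion,Unrestricted
Diamidafos,Banned
Diazoxon,Banned
Dimethyl chlorothiophosphate,Banned
Dioxabenzofos,Unrestricted
Dioxathion,Unrestricted
Diphenprofos,Unrestricted
Disulfoton sulfone oxygen analog,Unrestricted
Disulfoton sulfone,Banned
Disulfoton sulfoxide,Banned
DMCP,Banned
Endothion,Unrestricted
EPBP,Unrestricted
Ethephon,Unrestricted
Ethion dioxon,Unrestricted
"Ethion, O-analog",Banned
"Ethyl (2-mercaptoethyl) carbamate, S-ester of O,O-dimethyl phosphorodithioate",Restricted
Ethyl hydrogen 1-propylphosphonate,Unrestricted
"Famphur, O-analog",Unrestricted
Famphur,Unrestricted
Fenamiphos sulfone,Banned
Fenamiphos sulfoxide,Banned
Fenitrothion oxygen analog,Unrestricted
Fenthion oxon sulfone,Unrestricted
Fenthion oxon sulfoxide,Banned
Fenthion oxon,Banned
Fenthion sulfone,Unrestricted
Fenthion sulfoxide,Unrestricted
Fonofos oxon,Banned
Fosmethilan,Banned
Fospirate,Banned
Gardona (trans-isomer),Unrestricted
Hexylthiofos,Banned
Imicyafos,Banned
Inezin,Unrestricted
Iprobenfos,Banned
IPSP,Banned
Isazophos-methyl,Unrestricted
Isochlorthion,Unrestricted
isofenphos-methyl,Banned
Isomalathion (metabolite of malathion),Unrestricted
Isophos,Banned
Isothioate,Banned
Kitazine,Banned
Leptophos,Unrestricted
Lythidathion,Banned
Malaoxon,Unrestricted
Malathion dicarboxylic acid,Restricted
Mecarphon,Banned
Menazon,Banned
Merpofos,Unrestricted
Methyl paraoxon,Unrestricted
Methyl phenkapton,Banned
Methylisocyanothion,Unrestricted
Monocrotophos (isomer unspecified),Unrestricted
Morphothion,Restricted
Naled,Unrestricted
Naphthalophos,Unrestricted
"O,O,S-Trimethyl phosphorodithiate (as impurity)",Unrestricted
"O,O-diethyl O-naphthaloximido phosphorothioate",Unrestricted
"O,O-diethyl phosphoro chloridothionate",Banned
"O,O-Diethyl S-(4,6-dimethyl-2-pyrimidinyl) phosphorodithioate",Banned
"O,O-diethyl-O-phenyl phosphorothioate",Unrestricted
"O,O-dimethyl S-(2-(ethylsulfinyl)-1-methylethyl) phosphorothioate",Banned
O-(2-chloro-4-nitrophenyl) O-isopropyl ethylphosphonothioate,Unrestricted
O-(4-Nitrophenyl) O-phenyl methylphosphonothioate,Unrestricted
O-ethyl O-(4-(methylthio)phenyl) methylphosphonothioate,Banned
O-Ethyl O-methyl S-propylphosphorothioate (metabolite of ethoprop),Banned
O-Ethyl S-(4-methylphenyl) ethylphosphonodithioate,Banned
Oxydemeton methyl sulfone,Unrestricted
Paraoxon,Banned
Phenkapton,Banned
Phenthoate acid (as impurity),Unrestricted
Phorate oxygen analog sulfone,Unrestricted
Phorate oxygen analog,Banned
Phorate sulfone,Unrestricted
Phoratoxon sulfoxide,Banned
Phosacetim,Unrestricted
Phosfolan-methyl,Banned
Phosmet,Banned
Phosmetoxon,Banned
Phosnichlor,Unrestricted
phosphocarb,Unrestricted
"Phosphoric acid, 2-(1,1-dimethylethyl)-5-pyrimidinyl ethyl 1-methylethyl ester",Unrestricted
"Phosphorothioic acid, S-((6-chloro-2-oxo-3(2H)-benzoxazolyl) methyl) O,O-diethyl ester",Banned
Phostebupirim,Unrestricted
Phoxim-methyl,Banned
Piperophos,Unrestricted
"Pirimiphos ethyl, O-analog",Unrestricted
Pirimiphos-methyl,Banned
Primidophos,Unrestricted
Propoxon,Banned
Prothidathion,Banned
Prothion,Banned
Quadrafos,Unrestricted
Quinalphos-methyl,Unrestricted
Quinothion,Unrestricted
Quintiofos,Unrestricted
"S,S,S-tributyl phosphorotrithioate",Banned
"S-(1,1-Dimethylethyl) O-ethyl ethylphosphonothioate",Banned
"S-(4-(1,1-dimethylethyl)phenyl) O-ethyl ethylphosphonodithioate",Unrestricted
S-Methyl fenitrothion,Unrestricted
Sarin (Nonpesticidal chemical),Banned
Sophamide,Unrestricted
Sulprofos oxon,Banned
Temephos sulfoxide,Unrestricted
TEPP,Unrestricted
Terbufos oxon sulfone,Unrestricted
Terbufos sulfone,Unrestricted
Terbufos sulfoxide,Banned
Terbufos-O analog,Unrestricted
"Tetrachlorvinphos, Z-isomer",Unrestricted
Thion,Banned
"Thionazin, O-analog",Banned
Tolclofos-methyl,Unrestricted
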