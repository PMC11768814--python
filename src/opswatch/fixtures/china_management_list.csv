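name,level
Methamidophos,Banned
Parathion,Banned
Methyl parathion,Banned
Monocrotophos,Banned
Phosphoric acid,Banned
Fenamiphos,Banned
Fonofos,Banned
Phosfolan-methyl,Banned
Cadusafos,Banned
Coumaphos,Banned
Sulfotep,Banned
Terbufos,Banned
Methidathion,Banned
Phorate,Banned
Isofenphos-methyl,Banned
Isocarbophos,Banned
Ethoprophos,Banned
Omethoate,Restricted
Systox,Restricted
Posfolan-methyl,Restricted
Isazophos,Restricted
Acephate,Restricted
Dimethoate,Restricted
Chlorpyrifos,Restricted
Triazophos,Restricted
Fenthion,Unrestricted
Profenofos,Unrestricted
Dichlorvos,Unrestricted
Fosthiazate,Unrestricted
Phenthoate,Unrestricted
Dipterex,Unrestricted
Phoxim,Unrestricted
Quinalphos,Unrestricted
Fenitrothion,Unrestricted
Malathion,Unrestricted
Propetamphos,Unrestricted
Dicrotophos,Unrestricted
Azinphos-methyl,Unrestricted
EPN,Unrestricted
Pyrazophos,Unrestricted
Pyraclofos,Unrestricted
Propaphos,Unrestricted
Prothiofos,Unrestricted
Dichlofenthion,Unrestricted
Pyridiphenthion,Unrestricted
Fosthietan,Unrestricted
Tebupirimfos,Unrestricted
Chlorfenvinphos,Unrestricted
Diazinon,Unrestricted
Isoxathion,Unrestricted
Azinphos-ethyl,Unrestricted
Dibrom,Unrestricted
Famphur,Unrestricted
Phosalone,Unrestricted
Heptenophos,Unrestricted
Acethion,Unrestricted
Azamethiphos,Unrestricted
Chlorpyrifos-methyl,Unrestricted
Pirimiphos-methyl,Unrestricted
Thiometon,Unrestricted
Phosphocarb,Unrestricted
Sulprofos,Unrestricted
Chlormephos,Unrestricted
Chlorethoxyfos,Unrestricted
Isophenphos,Unrestricted
Mecarbam,Unrestricted
Naftalofos,Unrestricted
Tetrachlorvinphos,Unrestricted
Cyanophos,Unrestricted
Temephos,Unrestricted
Mevinphos,Unrestricted
Fensulfothion,Unrestricted
Mecarbam,Unrestricted
Phosemet,Unrestricted
Oxydemeton-methyl,Unrestricted
Disulfoton,Unrestricted
Ethion,Unrestricted
Thionazin,Unrestricted
Kitazine,Unrestricted
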