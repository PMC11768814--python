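name,composite_toxicity,printed_level
Tetrachlorvinphos,0.5886,Special Focus
Chlorfenvinphos,0.5080,Special Focus
Propaphos,0.5037,Focus
Naftalofos,0.4994,Focus
Phoxim,0.4840,Focus
Dichlorvos,0.4798,Focus
Temephos,0.4673,Focus
Propetamphos,0.4655,Focus
Dichlofenthion,0.4543,Focus
Chlorpyrifos-methyl,0.4538,Focus
Sulprofos,0.4511,Focus
Cyanophos,0.4506,Focus
Mevinphos,0.4494,Focus
EPN,0.4481,Focus
Dibrom,0.4361,Focus
Prothiofos,0.4358,Focus
Isoxathion,0.4349,Focus
Fenthion,0.4330,Focus
Azamethiphos,0.4322,Focus
Disulfoton,0.4308,Focus
Fenitrothion,0.4303,Focus
Quinalphos,0.4286,Focus
Phosalone,0.4267,Focus
Ethion,0.4242,Focus
Heptenophos,0.4240,Focus
Chlormephos,0.4232,Focus
Famphur,0.4227,General Focus
Azinphos-ethyl,0.4191,General Focus
Fosthietan,0.4174,General Focus
Dicrotophos,0.4167,General Focus
Pirimiphos-methyl,0.4158,General Focus
Thiometon,0.4156,General Focus
Oxydemeton-methyl,0.4151,General Focus
Pyraclofos,0.4146,General Focus
Diazinon,0.4138,General Focus
Pyridiphenthion,0.4076,General Focus
Azinphos-methyl,0.4059,General Focus
Isophenphos,0.4059,General Focus
Profenofos,0.4022,General Focus
Thionazin,0.4021,General Focus
Fensulfothion,0.4015,General Focus
Kitazine,0.4008,General Focus
Mecarbam,0.4003,General Focus
Phosemet,0.3878,General Focus
Fosthiazate,0.3871,General Focus
Acethion,0.3843,General Focus
Tebupirimfos,0.3823,General Focus
Phosphocarb,0.3785,General Focus
Chlorethoxyfos,0.3693,General Focus
Vamidothion,0.3599,General Focus
Pyrazophos,0.3502,General Focus
Dipterex,0.3479,General Focus
Phenthoate,0.3321,Secondary Focus
Malathion,0.3097,Secondary Focus
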