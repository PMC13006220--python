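product_id	component_class	generic_names	brand_names	start_quarter
FA	LABA/LAMA	Formoterol/aclidinium;Aclidinium/formoterol	DUAKLIR PRESSAIR	2019Q2
FG	LABA/LAMA	Formoterol/glycopyrrolate;Glycopyrrolate/formoterol	BEVESPI AEROSPHERE	2016Q2
IG	LABA/LAMA	Indacaterol/glycopyrrolate;Glycopyrrolate/indacaterol	UTIBRON	2015Q4
OT	LABA/LAMA	Olodaterol/tiotropium;Tiotropium/olodaterol	STIOLTO RESPIMAT	2015Q3
VU	LABA/LAMA	Vilanterol/umeclidinium;Umeclidinium/vilanterol	ANORO ELLIPTA	2014Q1
BGF	ICS/LABA/LAMA	Budesonide/glycopyrrolate/formoterol	BREZTRI AEROSPHERE	2020Q3
FUV	ICS/LABA/LAMA	Fluticasone/umeclidinium/vilanterol;Fluticasone furoate/umeclidinium/vilanterol	TRELEGY ELLIPTA	2017Q4
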