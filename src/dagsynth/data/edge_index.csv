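tail,head,bidirectional,confidence,provenance,notes
adol_sex,adol_alc,false,normal,hypothetical;seljamo_2006,
adol_substance,adol_alc,false,normal,hypothetical,
alc_initiation,adol_alc,false,normal,seljamo_2006,
family_structure,adol_alc,false,normal,seljamo_2006,
parental_alc_hist,adol_alc,false,normal,hypothetical;seljamo_2006,
adol_sex,adol_substance,false,normal,hypothetical,
alc_initiation,adol_substance,false,normal,idag_review,
parental_alc_hist,adol_substance,false,normal,hypothetical,
parental_alc_hist,alc_initiation,false,normal,seljamo_2006,
parental_alc_hist,family_structure,false,normal,seljamo_2006,
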