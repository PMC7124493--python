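node_a,node_b,provenance
adol_sex,alc_initiation,seljamo_2006
adol_sex,family_structure,idag_review
adol_sex,parental_alc_hist,hypothetical;seljamo_2006
adol_substance,family_structure,idag_review
alc_initiation,family_structure,seljamo_2006
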