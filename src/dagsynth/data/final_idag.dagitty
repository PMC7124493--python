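dag {
adol_alc [outcome]
adol_sex
adol_substance
alc_initiation
family_structure
parental_alc_hist [exposure]
adol_sex -> adol_alc
adol_substance -> adol_alc
alc_initiation -> adol_alc
family_structure -> adol_alc
parental_alc_hist -> adol_alc
adol_sex -> adol_substance
alc_initiation -> adol_substance
parental_alc_hist -> adol_substance
parental_alc_hist -> alc_initiation
parental_alc_hist -> family_structure
}
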