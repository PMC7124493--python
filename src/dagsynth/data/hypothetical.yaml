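study_id: hypothetical
citation: Hypothetical regression study of parental drinking history and offspring
  adolescent alcohol use
exposures:
- parental_alc_hist
outcomes:
- adol_alc
controls:
- adol_sex
- adol_substance
mediators: []
instruments: []
labels:
  parental_alc_hist: historical parental alcohol use
  adol_alc: adolescent alcohol use
  adol_sex: adolescent sex
  adol_substance: adolescent substance use
  alc_initiation: early alcohol initiation
  family_structure: family structure
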