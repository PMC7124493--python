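study_id,tail,head,criterion,verdict,rationale,reference,reviewer,confidence,timestamp
idag_review,family_structure,adol_sex,temporality,yes,family structure changes follow sex assignment in time only for later composition,,r1,normal,
idag_review,family_structure,adol_sex,face_validity,no,family composition cannot influence sex assignment,,r1,normal,
idag_review,adol_sex,family_structure,temporality,yes,sex assignment precedes family composition changes,,r1,normal,
idag_review,adol_sex,family_structure,face_validity,yes,conceivable pathway,,r1,normal,
idag_review,adol_sex,family_structure,recourse_to_theory,unknown,no theory advanced,,r1,normal,
idag_review,adol_sex,family_structure,counterfactual,no,no expected family-structure contrast between counterfactual sexes,,r1,normal,
idag_review,alc_initiation,adol_substance,temporality,yes,early alcohol initiation precedes other substance use,,r1,normal,
idag_review,alc_initiation,adol_substance,face_validity,yes,early initiation plausibly gateways into other substances,,r1,normal,
idag_review,alc_initiation,adol_substance,recourse_to_theory,yes,gateway accounts,gateway hypothesis,r1,normal,
idag_review,alc_initiation,adol_substance,counterfactual,yes,expected substance use differs under counterfactual initiation ages,,r1,normal,
idag_review,adol_substance,alc_initiation,temporality,no,later substance use cannot precede early initiation,,r1,normal,
idag_review,family_structure,adol_substance,temporality,yes,family structure precedes adolescent substance use,,r1,normal,
idag_review,family_structure,adol_substance,face_validity,yes,conceivable pathway,,r1,normal,
idag_review,family_structure,adol_substance,recourse_to_theory,unknown,inferred: no theory advanced,,r1,normal,
idag_review,family_structure,adol_substance,counterfactual,no,inferred: no substance-use contrast expected under counterfactual family structures,,r1,normal,
idag_review,adol_substance,family_structure,temporality,no,adolescent substance use cannot precede established family structure,,r1,normal,
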