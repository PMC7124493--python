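study_id,tail,head,criterion,verdict,rationale,reference,reviewer,confidence,timestamp
hypothetical,parental_alc_hist,adol_alc,temporality,yes,parental drinking history precedes offspring adolescence,,r1,normal,
hypothetical,parental_alc_hist,adol_alc,face_validity,yes,parental modelling of drinking is plausible,,r1,normal,
hypothetical,parental_alc_hist,adol_alc,recourse_to_theory,yes,social learning of drinking behaviour,social learning theory,r1,normal,
hypothetical,parental_alc_hist,adol_alc,counterfactual,yes,setting all parents to heavy historical use raises expected adolescent drinking frequency,,r1,normal,
hypothetical,adol_alc,parental_alc_hist,temporality,no,adolescent drinking cannot precede historical parental use,,r1,normal,
hypothetical,adol_sex,parental_alc_hist,temporality,no,offspring sex is assigned after the parental drinking history began,,r1,normal,
hypothetical,parental_alc_hist,adol_sex,temporality,yes,historical parental use precedes sex assignment,,r1,normal,
hypothetical,parental_alc_hist,adol_sex,face_validity,no,implausible that parental alcohol use influences offspring sex assignment despite temporal ordering,,r1,normal,
hypothetical,adol_sex,adol_alc,temporality,yes,sex assigned at birth precedes adolescent drinking,,r1,normal,
hypothetical,adol_sex,adol_alc,face_validity,yes,sex differences in adolescent drinking are plausible,,r1,normal,
hypothetical,adol_sex,adol_alc,recourse_to_theory,unknown,no specific theory cited; absence of theory is not absence of effect,,r1,normal,
hypothetical,adol_sex,adol_alc,counterfactual,yes,expected drinking frequency differs between all-male and all-female counterfactual exposures,,r1,normal,
hypothetical,adol_alc,adol_sex,temporality,no,adolescent drinking cannot precede sex assignment,,r1,normal,
hypothetical,adol_substance,parental_alc_hist,temporality,no,adolescent substance use cannot precede historical parental alcohol use,,r1,normal,
hypothetical,parental_alc_hist,adol_substance,temporality,yes,parental history precedes offspring substance use,,r1,normal,
hypothetical,parental_alc_hist,adol_substance,face_validity,yes,household exposure to substance use is plausible,,r1,normal,
hypothetical,parental_alc_hist,adol_substance,recourse_to_theory,yes,common liability to addiction,common liability model,r1,normal,
hypothetical,parental_alc_hist,adol_substance,counterfactual,yes,expected substance use differs under counterfactual parental histories,,r1,normal,
hypothetical,adol_substance,adol_alc,temporality,yes,substance use measured before the drinking outcome,,r1,normal,
hypothetical,adol_substance,adol_alc,face_validity,yes,gateway between substances is plausible,,r1,normal,
hypothetical,adol_substance,adol_alc,recourse_to_theory,yes,gateway/common liability accounts,gateway hypothesis,r1,normal,
hypothetical,adol_substance,adol_alc,counterfactual,yes,expected drinking frequency differs under counterfactual substance use,,r1,normal,
hypothetical,adol_alc,adol_substance,temporality,yes,measurements are contemporaneous in part,,r1,normal,
hypothetical,adol_alc,adol_substance,face_validity,yes,reverse pathway conceivable,,r1,normal,
hypothetical,adol_alc,adol_substance,recourse_to_theory,unknown,inferred: no theory advanced for the reverse pathway,,r1,normal,
hypothetical,adol_alc,adol_substance,counterfactual,no,under the study's measurement order no outcome contrast is expected,,r1,normal,
hypothetical,adol_sex,adol_substance,temporality,yes,sex assignment precedes adolescent substance use,,r1,normal,
hypothetical,adol_sex,adol_substance,face_validity,yes,sex differences in substance use are plausible,,r1,normal,
hypothetical,adol_sex,adol_substance,recourse_to_theory,unknown,inferred: no specific theory cited,,r1,normal,
hypothetical,adol_sex,adol_substance,counterfactual,yes,expected substance use differs between counterfactual sexes,,r1,normal,
hypothetical,adol_substance,adol_sex,temporality,no,substance use cannot precede sex assignment,,r1,normal,
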