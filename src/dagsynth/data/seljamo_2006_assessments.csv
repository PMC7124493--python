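study_id,tail,head,criterion,verdict,rationale,reference,reviewer,confidence,timestamp
seljamo_2006,parental_alc_hist,adol_alc,temporality,yes,parental drinking history precedes offspring adolescence,,r1,normal,
seljamo_2006,parental_alc_hist,adol_alc,face_validity,yes,parental modelling of drinking is plausible,,r1,normal,
seljamo_2006,parental_alc_hist,adol_alc,recourse_to_theory,yes,social learning of drinking behaviour,social learning theory,r1,normal,
seljamo_2006,parental_alc_hist,adol_alc,counterfactual,yes,expected adolescent drinking differs under counterfactual parental histories,,r1,normal,
seljamo_2006,adol_alc,parental_alc_hist,temporality,no,adolescent drinking cannot precede historical parental use,,r1,normal,
seljamo_2006,alc_initiation,parental_alc_hist,temporality,no,early adolescent initiation cannot precede historical parental use,,r1,normal,
seljamo_2006,parental_alc_hist,alc_initiation,temporality,yes,parental history precedes offspring initiation,,r1,normal,
seljamo_2006,parental_alc_hist,alc_initiation,face_validity,yes,parental drinking shapes availability and norms,,r1,normal,
seljamo_2006,parental_alc_hist,alc_initiation,recourse_to_theory,yes,inferred: socialisation accounts,,r1,normal,
seljamo_2006,parental_alc_hist,alc_initiation,counterfactual,yes,expected initiation age differs under counterfactual parental histories,,r1,normal,
seljamo_2006,alc_initiation,adol_alc,temporality,yes,early initiation precedes drinking at follow-up,,r1,normal,
seljamo_2006,alc_initiation,adol_alc,face_validity,yes,earlier initiation plausibly entrenches use,,r1,normal,
seljamo_2006,alc_initiation,adol_alc,recourse_to_theory,yes,early-onset risk accounts,,r1,normal,
seljamo_2006,alc_initiation,adol_alc,counterfactual,yes,expected follow-up drinking differs under counterfactual initiation ages,,r1,normal,
seljamo_2006,adol_alc,alc_initiation,temporality,no,follow-up drinking cannot precede initiation,,r1,normal,
seljamo_2006,family_structure,parental_alc_hist,temporality,no,family structure at follow-up cannot precede the parental drinking history,,r1,normal,
seljamo_2006,parental_alc_hist,family_structure,temporality,yes,parental drinking precedes later family composition,,r1,normal,
seljamo_2006,parental_alc_hist,family_structure,face_validity,yes,problem drinking plausibly influences family dissolution,,r1,normal,
seljamo_2006,parental_alc_hist,family_structure,recourse_to_theory,unknown,inferred: no specific theory cited,,r1,normal,
seljamo_2006,parental_alc_hist,family_structure,counterfactual,yes,expected family structure differs under counterfactual parental histories,,r1,normal,
seljamo_2006,family_structure,adol_alc,temporality,yes,family structure precedes the drinking outcome,,r1,normal,
seljamo_2006,family_structure,adol_alc,face_validity,yes,family composition plausibly affects adolescent drinking,,r1,normal,
seljamo_2006,family_structure,adol_alc,recourse_to_theory,yes,family systems accounts,,r1,normal,
seljamo_2006,family_structure,adol_alc,counterfactual,yes,expected drinking differs under counterfactual family structures,,r1,normal,
seljamo_2006,adol_alc,family_structure,temporality,no,outcome measured last in follow-up,,r1,normal,
seljamo_2006,adol_sex,parental_alc_hist,temporality,no,offspring sex is assigned after the parental drinking history began,,r1,normal,
seljamo_2006,parental_alc_hist,adol_sex,temporality,yes,historical parental use precedes sex assignment,,r1,normal,
seljamo_2006,parental_alc_hist,adol_sex,face_validity,no,implausible that parental alcohol use influences offspring sex assignment,,r1,normal,
seljamo_2006,adol_sex,adol_alc,temporality,yes,sex assigned at birth precedes adolescent drinking,,r1,normal,
seljamo_2006,adol_sex,adol_alc,face_validity,yes,sex differences in adolescent drinking are plausible,,r1,normal,
seljamo_2006,adol_sex,adol_alc,recourse_to_theory,unknown,no specific theory cited,,r1,normal,
seljamo_2006,adol_sex,adol_alc,counterfactual,yes,expected drinking differs between counterfactual sexes,,r1,normal,
seljamo_2006,adol_alc,adol_sex,temporality,no,adolescent drinking cannot precede sex assignment,,r1,normal,
seljamo_2006,family_structure,alc_initiation,temporality,yes,family structure precedes adolescent initiation,,r1,normal,
seljamo_2006,family_structure,alc_initiation,face_validity,yes,conceivable pathway,,r1,normal,
seljamo_2006,family_structure,alc_initiation,recourse_to_theory,unknown,inferred: no theory advanced,,r1,normal,
seljamo_2006,family_structure,alc_initiation,counterfactual,no,inferred: no initiation contrast expected under counterfactual family structures in this design,,r1,normal,
seljamo_2006,alc_initiation,family_structure,temporality,no,adolescent initiation cannot precede established family structure,,r1,normal,
seljamo_2006,adol_sex,alc_initiation,temporality,yes,sex precedes initiation,,r1,normal,
seljamo_2006,adol_sex,alc_initiation,face_validity,yes,conceivable pathway,,r1,normal,
seljamo_2006,adol_sex,alc_initiation,recourse_to_theory,unknown,inferred: no theory advanced,,r1,normal,
seljamo_2006,adol_sex,alc_initiation,counterfactual,no,inferred: no initiation-age contrast expected between counterfactual sexes under this measurement,,r1,normal,
seljamo_2006,alc_initiation,adol_sex,temporality,no,initiation cannot precede sex assignment,,r1,normal,
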