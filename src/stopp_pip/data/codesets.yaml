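# Code-set fixture: named ATC / ICD prefix sets.
#
# STOPP criteria are published without terminology bindings, so these
# mappings are conventional reconstructions: the drug-class prefixes are
# standard ATC classes and the diagnosis groups are common ICD-9 /
# ICD-10 groupings.  They are configuration, not clinical guidance, and
# clinical fidelity of any individual mapping is not load-bearing for
# the engine mechanics.
#
# ICD-9 prefixes are matched against the literal stored string (dot
# included): "427.31" matches "427.31" but not "42731".

# --- drug-diagnosis concordance probe sets --------------------------------
tiotropium:
  system: ATC
  prefixes: [R03BB04]
levothyroxine:
  system: ATC
  prefixes: [H03AA01]
anti_gout:
  system: ATC
  prefixes: [M04A]
diabetes_icd9:
  system: ICD9
  prefixes: ["250"]
diabetes_icd10:
  system: ICD10
  prefixes: [E10, E11, E12, E13, E14]
copd_icd9:
  system: ICD9
  prefixes: ["491", "492", "496"]
copd_icd10:
  system: ICD10
  prefixes: [J44]
hypothyroidism_icd9:
  system: ICD9
  prefixes: ["244"]
hypothyroidism_icd10:
  system: ICD10
  prefixes: [E03]
gout_icd9:
  system: ICD9
  prefixes: ["274"]
gout_icd10:
  system: ICD10
  prefixes: [M10]

# --- rule anchor drug classes ---------------------------------------------
benzodiazepine_anxiolytics:
  system: ATC
  prefixes: [N05BA]
benzodiazepine_hypnotics:
  system: ATC
  prefixes: [N05CD]
phenothiazine_antipsychotics:
  system: ATC
  prefixes: [N05AA]
anticholinergic_antiparkinsonians:
  system: ATC
  prefixes: [N04AA]
tricyclic_antidepressants:
  system: ATC
  prefixes: [N06AA]
opioids_natural:
  system: ATC
  prefixes: [N02AA]
pethidine_class_opioids:
  system: ATC
  prefixes: [N02AB]
acetic_acid_nsaids:
  system: ATC
  prefixes: [M01AB]
propionic_nsaids:
  system: ATC
  prefixes: [M01AE]
oxicam_nsaids:
  system: ATC
  prefixes: [M01AC]
digitalis_glycosides:
  system: ATC
  prefixes: [C01AA]
nonselective_beta_blockers:
  system: ATC
  prefixes: [C07AA]
verapamil_type_ccb:
  system: ATC
  prefixes: [C08DA]
loop_diuretics:
  system: ATC
  prefixes: [C03CA]
thiazide_diuretics:
  system: ATC
  prefixes: [C03AA]
ssris:
  system: ATC
  prefixes: [N06AB]
belladonna_antimuscarinics:
  system: ATC
  prefixes: [A03BA]
urinary_antimuscarinics:
  system: ATC
  prefixes: [G04BD]
first_generation_antihistamines:
  system: ATC
  prefixes: [R06AA]
class_ia_antiarrhythmics:
  system: ATC
  prefixes: [C01BA]
vitamin_k_antagonists:
  system: ATC
  prefixes: [B01AA]
antiplatelet_agents:
  system: ATC
  prefixes: [B01AC]
methyldopa:
  system: ATC
  prefixes: [C02AB]
clonidine_type_antihypertensives:
  system: ATC
  prefixes: [C02AC]
long_acting_sulfonylureas:
  system: ATC
  prefixes: [A10BB]
central_muscle_relaxants:
  system: ATC
  prefixes: [M03BX]
opioid_antitussives:
  system: ATC
  prefixes: [R05DA]
barbiturates:
  system: ATC
  prefixes: [N03AA]
stimulant_laxatives:
  system: ATC
  prefixes: [A06AB]
long_acting_nitrates:
  system: ATC
  prefixes: [C01DA]
phenothiazine_like_atypicals:
  system: ATC
  prefixes: [N05AH]
systemic_estrogens:
  system: ATC
  prefixes: [G03CA]
ergot_alkaloids:
  system: ATC
  prefixes: [N02CA]
peripheral_vasodilators:
  system: ATC
  prefixes: [C04AX]
systemic_corticosteroids:
  system: ATC
  prefixes: [H02AB]
coxibs:
  system: ATC
  prefixes: [M01AH]
xanthines:
  system: ATC
  prefixes: [R03DA]
potassium_supplements:
  system: ATC
  prefixes: [A12BA]
alpha_blockers_urological:
  system: ATC
  prefixes: [G04CA]
psychostimulants:
  system: ATC
  prefixes: [N06BA]

# --- rule trigger conditions (problem-list diagnosis groups) --------------
falls_history:
  system: ICD9
  prefixes: [E888, "V15.88"]
sleep_apnoea:
  system: ICD9
  prefixes: ["327"]
parkinsonism:
  system: ICD9
  prefixes: ["332"]
dementia:
  system: ICD9
  prefixes: ["290"]
glaucoma:
  system: ICD9
  prefixes: ["365"]
chronic_constipation:
  system: ICD9
  prefixes: ["564"]
chronic_kidney_disease:
  system: ICD9
  prefixes: ["585"]
gastric_ulcer:
  system: ICD9
  prefixes: ["531"]
heart_failure:
  system: ICD9
  prefixes: ["428"]
hypertension:
  system: ICD9
  prefixes: ["401"]
heart_block:
  system: ICD9
  prefixes: ["426"]
asthma:
  system: ICD9
  prefixes: ["493"]
bradycardia:
  system: ICD9
  prefixes: ["427.81"]
urinary_incontinence:
  system: ICD9
  prefixes: ["788.3"]
hypokalaemia:
  system: ICD9
  prefixes: ["276.8"]
hyponatraemia:
  system: ICD9
  prefixes: ["276.1"]
prostatic_hypertrophy:
  system: ICD9
  prefixes: ["600"]
delirium:
  system: ICD9
  prefixes: ["293"]
cognitive_impairment:
  system: ICD9
  prefixes: ["294"]
atrial_fibrillation:
  system: ICD9
  prefixes: ["427.31"]
gi_bleeding:
  system: ICD9
  prefixes: ["578"]
peptic_ulcer:
  system: ICD9
  prefixes: ["533"]
depression:
  system: ICD9
  prefixes: ["296"]
orthostatic_hypotension:
  system: ICD9
  prefixes: ["458"]
hypoglycaemia:
  system: ICD9
  prefixes: ["251"]
bladder_outflow_obstruction:
  system: ICD9
  prefixes: ["596"]
bronchiectasis:
  system: ICD9
  prefixes: ["494"]
insomnia_nonorganic:
  system: ICD9
  prefixes: ["307.4"]
intestinal_obstruction:
  system: ICD9
  prefixes: ["560"]
syncope:
  system: ICD9
  prefixes: ["780.2"]
cerebral_degeneration:
  system: ICD9
  prefixes: ["331"]
breast_cancer:
  system: ICD9
  prefixes: ["174"]
peripheral_vascular_disease:
  system: ICD9
  prefixes: ["443"]
cerebrovascular_sequelae:
  system: ICD9
  prefixes: ["438"]
osteoarthritis:
  system: ICD9
  prefixes: ["715"]
ischaemic_heart_disease:
  system: ICD9
  prefixes: ["414"]
tachycardia:
  system: ICD9
  prefixes: ["785.0"]
hyperkalaemia:
  system: ICD9
  prefixes: ["276.7"]
urinary_frequency:
  system: ICD9
  prefixes: ["788.4"]
hypertensive_heart_disease:
  system: ICD9
  prefixes: ["402"]
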