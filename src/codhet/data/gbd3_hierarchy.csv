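cause_id,cause_name,level,parent_id
cmn,"Communicable, maternal, neonatal, and nutritional diseases",1,
ncd,Non-communicable diseases,1,
inj,Injuries,1,
hiv_std,HIV/AIDS and sexually transmitted infections,2,cmn
hiv,HIV/AIDS,3,hiv_std
syphilis,Syphilis,3,hiv_std
chlamydia,Chlamydial infection,3,hiv_std
hiv_std_oth1,Other hiv/aids and sexually transmitted infections,3,hiv_std
resp_tb,Respiratory infections and tuberculosis,2,cmn
tb,Tuberculosis,3,resp_tb
lri,Lower respiratory infections,3,resp_tb
uri,Upper respiratory infections,3,resp_tb
otitis,Otitis media,3,resp_tb
resp_tb_oth1,Other respiratory infections and tuberculosis,3,resp_tb
enteric,Enteric infections,2,cmn
diarrheal,Diarrhoeal diseases,3,enteric
typhoid,Typhoid and paratyphoid,3,enteric
int_inf,Invasive non-typhoidal Salmonella,3,enteric
enteric_oth1,Other enteric infections,3,enteric
ntd_malaria,Neglected tropical diseases and malaria,2,cmn
malaria,Malaria,3,ntd_malaria
chagas,Chagas disease,3,ntd_malaria
leish,Leishmaniasis,3,ntd_malaria
dengue,Dengue,3,ntd_malaria
rabies,Rabies,3,ntd_malaria
ntd_malaria_oth1,Other neglected tropical diseases and malaria,3,ntd_malaria
oth_infect,Other infectious diseases,2,cmn
meningitis,Meningitis,3,oth_infect
encephalitis,Encephalitis,3,oth_infect
measles,Measles,3,oth_infect
tetanus,Tetanus,3,oth_infect
varicella,Varicella and herpes zoster,3,oth_infect
oth_infect_oth1,Other other infectious diseases,3,oth_infect
mat_neo,Maternal and neonatal disorders,2,cmn
maternal,Maternal disorders,3,mat_neo
neonatal,Neonatal disorders,3,mat_neo
mat_neo_oth1,Other maternal and neonatal disorders,3,mat_neo
nutrition,Nutritional deficiencies,2,cmn
pem,Protein-energy malnutrition,3,nutrition
iodine,Iodine deficiency,3,nutrition
vit_a,Vitamin A deficiency,3,nutrition
nutrition_oth1,Other nutritional deficiencies,3,nutrition
neoplasms,Neoplasms,2,ncd
leukaemia,Leukaemia,3,neoplasms
lung_ca,"Tracheal, bronchus, and lung cancer",3,neoplasms
colorect_ca,Colon and rectum cancer,3,neoplasms
stomach_ca,Stomach cancer,3,neoplasms
liver_ca,Liver cancer,3,neoplasms
breast_ca,Breast cancer,3,neoplasms
cervical_ca,Cervical cancer,3,neoplasms
prostate_ca,Prostate cancer,3,neoplasms
pancreatic_ca,Pancreatic cancer,3,neoplasms
esoph_ca,Oesophageal cancer,3,neoplasms
bladder_ca,Bladder cancer,3,neoplasms
brain_ca,Brain and nervous system cancer,3,neoplasms
ovarian_ca,Ovarian cancer,3,neoplasms
nhl,Non-Hodgkin lymphoma,3,neoplasms
hodgkin,Hodgkin lymphoma,3,neoplasms
melanoma,Malignant skin melanoma,3,neoplasms
lip_oral_ca,Lip and oral cavity cancer,3,neoplasms
kidney_ca,Kidney cancer,3,neoplasms
uterine_ca,Uterine cancer,3,neoplasms
thyroid_ca,Thyroid cancer,3,neoplasms
larynx_ca,Larynx cancer,3,neoplasms
mesothelioma,Mesothelioma,3,neoplasms
mm,Multiple myeloma,3,neoplasms
neoplasms_oth1,Other neoplasms,3,neoplasms
neoplasms_oth2,Other neoplasms,3,neoplasms
cardio,Cardiovascular diseases,2,ncd
ihd,Ischaemic heart disease,3,cardio
stroke,Stroke,3,cardio
htn_hd,Hypertensive heart disease,3,cardio
rhd,Rheumatic heart disease,3,cardio
cardiomyopathy,Cardiomyopathy and myocarditis,3,cardio
afib,Atrial fibrillation and flutter,3,cardio
aortic_an,Aortic aneurysm,3,cardio
pad,Peripheral artery disease,3,cardio
endocarditis,Endocarditis,3,cardio
non_rhd_valve,Non-rheumatic valvular heart disease,3,cardio
cardio_oth1,Other cardiovascular diseases,3,cardio
cardio_oth2,Other cardiovascular diseases,3,cardio
chronic_resp,Chronic respiratory diseases,2,ncd
copd,Chronic obstructive pulmonary disease,3,chronic_resp
asthma,Asthma,3,chronic_resp
ild,Interstitial lung disease and pulmonary sarcoidosis,3,chronic_resp
pneumoconiosis,Pneumoconiosis,3,chronic_resp
chronic_resp_oth1,Other chronic respiratory diseases,3,chronic_resp
chronic_resp_oth2,Other chronic respiratory diseases,3,chronic_resp
digestive,Digestive diseases,2,ncd
cirrhosis,Cirrhosis and other chronic liver diseases,3,digestive
pud,Peptic ulcer disease,3,digestive
pancreatitis,Pancreatitis,3,digestive
ibd,Inflammatory bowel disease,3,digestive
gallbladder,Gallbladder and biliary diseases,3,digestive
ileus,Paralytic ileus and intestinal obstruction,3,digestive
digestive_oth1,Other digestive diseases,3,digestive
neuro,Neurological disorders,2,ncd
alzheimers,Alzheimer's disease and other dementias,3,neuro
parkinsons,Parkinson's disease,3,neuro
epilepsy,Epilepsy,3,neuro
ms,Multiple sclerosis,3,neuro
motor_neuron,Motor neuron disease,3,neuro
neuro_oth1,Other neurological disorders,3,neuro
neuro_oth2,Other neurological disorders,3,neuro
mental,Mental disorders,2,ncd
eating_dis,Eating disorders,3,mental
conduct,Conduct disorder,3,mental
mental_oth1,Other mental disorders,3,mental
substance,Substance use disorders,2,ncd
alcohol_use,Alcohol use disorders,3,substance
drug_use,Drug use disorders,3,substance
substance_oth1,Other substance use disorders,3,substance
diabetes_ckd,Diabetes and kidney diseases,2,ncd
diabetes,Diabetes mellitus,3,diabetes_ckd
ckd,Chronic kidney disease,3,diabetes_ckd
nephritis,Acute glomerulonephritis,3,diabetes_ckd
diabetes_ckd_oth1,Other diabetes and kidney diseases,3,diabetes_ckd
skin,Skin and subcutaneous diseases,2,ncd
skin_bact,Bacterial skin diseases,3,skin
decubitus,Decubitus ulcer,3,skin
skin_oth1,Other skin and subcutaneous diseases,3,skin
sense,Sense organ diseases,2,ncd
hearing,Age-related and other hearing loss,3,sense
sense_oth1,Other sense organ diseases,3,sense
musculo,Musculoskeletal disorders,2,ncd
ra,Rheumatoid arthritis,3,musculo
gout,Gout,3,musculo
musculo_oth1,Other musculoskeletal disorders,3,musculo
oth_ncd,Other non-communicable diseases,2,ncd
congenital,Congenital birth defects,3,oth_ncd
hemoglobin,Haemoglobinopathies and haemolytic anaemias,3,oth_ncd
endocrine,"Endocrine, metabolic, blood, and immune disorders",3,oth_ncd
urinary,Urinary diseases and male infertility,3,oth_ncd
gynecological,Gynaecological diseases,3,oth_ncd
oral,Oral disorders,3,oth_ncd
sids,Sudden infant death syndrome,3,oth_ncd
oth_ncd_oth1,Other other non-communicable diseases,3,oth_ncd
transport,Transport injuries,2,inj
road,Road injuries,3,transport
oth_transport,Other transport injuries,3,transport
transport_oth1,Other transport injuries,3,transport
unintentional,Unintentional injuries,2,inj
falls,Falls,3,unintentional
drowning,Drowning,3,unintentional
fire,"Fire, heat, and hot substances",3,unintentional
poisoning,Poisonings,3,unintentional
mech_forces,Exposure to mechanical forces,3,unintentional
nature,Exposure to forces of nature,3,unintentional
env_heat_cold,Environmental heat and cold exposure,3,unintentional
animal,Animal contact,3,unintentional
foreign_body,Foreign body,3,unintentional
med_adverse,Adverse effects of medical treatment,3,unintentional
unintentional_oth1,Other unintentional injuries,3,unintentional
selfharm_violence,Self-harm and interpersonal violence,2,inj
self_harm,Self-harm,3,selfharm_violence
violence,Interpersonal violence,3,selfharm_violence
conflict,Conflict and terrorism,3,selfharm_violence
selfharm_violence_oth1,Other self-harm and interpersonal violence,3,selfharm_violence
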