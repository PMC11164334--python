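use_phrase,category_id
abdominal pains,dig
abdominal pains diarrhea,dig
adult squirt,dig
anaesthetic,sed
anemia,blood
anti fungal,skin
anti pyretic,cold
anti-bacterial,blood
anti-cancer,met
anti-fungal,skin
anti-leg tumult,mus
anti-tumult,dig
anti-tumult in stomach,dig
anti-virus,cold
aperients,dig
appetizing,flav
arthritis,mus
asthma,resp
backache,mus
blood cholesterol,met
blood coagulation,blood
blood fat,met
blood problem,blood
blood purifier,blood
body detoxification,met
bone and joint pains,mus
bronchitis,resp
burn,skin
cardiac distress,card
carminative,dig
carminative in children,dig
child squirt,dig
constipation,dig
cough,cold
decrease blood sugar level,met
detoxification,met
diabetes,met
digestive,dig
digestive problem,dig
digestive system,dig
dilution of blood,blood
disinfectant,blood
diuretic,met
diuretic infection,met
dysentery,dig
eatable color,flav
epilepsy,ner
eye problem,eye
eye tonic,eye
febrifuge,cold
fever,cold
flavor,flav
food digestion,dig
fracture,mus
gallbladder diseases,liver
gastric discomfort,dig
gastritis,dig
hair tonic,skin
headache,mus
heat of body,cold
hemophilia,blood
influenza,cold
intestinal infections,dig
iron supply,met
jaundice,liver
laxative,dig
lipotropic,met
liver cleaner,liver
liver cysts,liver
liver problem,liver
menstrual pains,gyn
menstruation,gyn
menstruation additive,gyn
nausea,dig
nerve tonic,ner
never tonic,ner
parasite repellent,dig
pertussis,resp
prevention of blood coagulation,blood
regulatory of menstruation,gyn
remove inflammation of the skin,skin
remove rash from skin,skin
rheumatism,mus
sedative,sed
sexual desire,gyn
skin and hair disorders,skin
skin burn,skin
skin rash,skin
skin whitening,skin
slimming,met
stomach bleeding,dig
stomach ulcers,dig
stomachache,dig
sudorific,cold
supply of vitamin,met
syrup,flav
throat infection,cold
throat pains,cold
tonic,flav
toothache,mus
toxication,liver
ulcer,dig
urinary disease,met
urinary infection,met
urinary stone,met
vitamins and minerals,met
wound healing,blood
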