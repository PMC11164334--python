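category_id,name
dig,Digestive system
met,Metabolic (Diabetes and diuretic)
ner,Nervous system
skin,Skin & hair
cold,Cold/flu/fever
resp,Respiratory system
flav,Flavor/Appetizing
eye,Eye problems
sed,Sedative
gyn,Gynecology
card,Cardiac system
mus,Musculoskeletal disorders
blood,Blood/wound
liver,Liver problems
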