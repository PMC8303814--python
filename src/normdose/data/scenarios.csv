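category,eu_class,location,normal_time,overuse_time,overuse_condition,pathways
pillow,Existing Products,"Head, neck",7 h 50 min,9 h 50 min,sickness/oversleeping,inhalation
latex_mattress,Existing Products,Whole body,7 h 50 min,9 h 50 min,sickness/oversleeping,inhalation
clothing,Existing Products,Depending on usage,24 h,1 day 2 h,overuse,inhalation
necklace,Existing Products,Neck,8 h 7 min,10 h 7 min,overuse,inhalation
bracelet,Existing Products,Hand,8 h 7 min,10 h 7 min,overuse,inhalation
amnion_patch,Existing Products,Body for wound covering,8 h 7 min,10 h 7 min,overuse,inhalation;ingestion
cosmetics,Existing Products,Face and body,8 h 7 min,10 h 7 min,accidental ingestion,ingestion
diapers,Existing Products,Depending on usage,20 min,2 h 20 min,overuse,inhalation
slippers,Existing Products,Foot wares,5 h 1 min,7 h 1 min,overuse,inhalation
health_supplements,Existing Products,"Waist, abdomen, etc.",5 h 1 min,7 h 1 min,overuse,external;inhalation
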