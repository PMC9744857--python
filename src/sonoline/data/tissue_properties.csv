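name,density_kg_m3,speed_m_s,length_m,reference
epidermis,1190,1624,0.0002,literature estimate (skin acoustic constants; anatomy-based thickness)
dermis,1116,1624,0.0020,literature estimate
subcutaneous_tissue,911,1440,0.0050,literature estimate (subcutaneous fat)
vagus_trunk_cervical,1075,1558,0.15,literature nerve constants; anatomy-approximated span
lrln_descending,1075,1558,0.18,literature nerve constants; anatomy-approximated span
lrln_ascending,1075,1558,0.16,literature nerve constants; anatomy-approximated span
lrln_terminal,1075,1558,0.04,literature nerve constants; anatomy-approximated span
vagus_trunk_thoracic,1075,1558,0.12,literature nerve constants; anatomy-approximated span
cardiac_branch,1075,1558,0.10,literature nerve constants; anatomy-approximated span
anterior_vagal_trunk,1075,1558,0.18,literature nerve constants; anatomy-approximated span
esophageal_plexus,1075,1558,0.08,literature nerve constants; anatomy-approximated span
celiac_branch,1075,1558,0.08,literature nerve constants; anatomy-approximated span
celiac_plexus,1075,1558,0.03,literature nerve constants; anatomy-approximated span
splenic_nerve,1075,1558,0.04,literature nerve constants; anatomy-approximated span
hepatic_branch,1075,1558,0.12,literature nerve constants; anatomy-approximated span
hepatic_plexus,1075,1558,0.04,literature nerve constants; anatomy-approximated span
gastric_branch,1075,1558,0.08,literature nerve constants; anatomy-approximated span
gastric_plexus,1075,1558,0.04,literature nerve constants; anatomy-approximated span
intercostal_muscle,1090,1588,0.015,literature muscle constants
diaphragm,1090,1588,0.005,literature muscle constants
spleen_capsule,1120,1613,0.001,literature connective-tissue constants
spleen,1089,1567,0.06,literature estimate
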