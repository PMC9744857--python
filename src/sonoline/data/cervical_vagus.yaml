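# Cervical vagus stimulation topology (mirrors sonoline.network.cervical_vagus_model).
# Dialect: `source` names the root node; `lines` is an ordered adjacency list of
# transmission lines (tissue must exist in the tissue-property table); leaves get
# matched loads automatically; `terminal_labels` names the measured terminals.
name: cervical_vagus
source: transducer
lines:
  - {id: T1, tissue: epidermis, from: transducer, to: n1}
  - {id: T2, tissue: dermis, from: n1, to: n2}
  - {id: T3, tissue: subcutaneous_tissue, from: n2, to: n3}
  - {id: T4, tissue: vagus_trunk_cervical, from: n3, to: lrln_branch}
  - {id: T5, tissue: lrln_descending, from: lrln_branch, to: n5}
  - {id: T6, tissue: lrln_ascending, from: n5, to: n6}
  - {id: T7, tissue: lrln_terminal, from: n6, to: lrln_end}
  - {id: T8, tissue: vagus_trunk_thoracic, from: lrln_branch, to: cardiac_branch_pt}
  - {id: T9, tissue: cardiac_branch, from: cardiac_branch_pt, to: cardiac_end}
  - {id: T10, tissue: anterior_vagal_trunk, from: cardiac_branch_pt, to: n8}
  - {id: T11, tissue: esophageal_plexus, from: n8, to: esophageal_split}
  - {id: T12, tissue: celiac_branch, from: esophageal_split, to: n10}
  - {id: T13, tissue: celiac_plexus, from: n10, to: n11}
  - {id: T14, tissue: splenic_nerve, from: n11, to: splenic_end}
  - {id: T15, tissue: hepatic_branch, from: esophageal_split, to: n12}
  - {id: T16, tissue: hepatic_plexus, from: n12, to: hepatic_end}
  - {id: T17, tissue: gastric_branch, from: esophageal_split, to: n13}
  - {id: T18, tissue: gastric_plexus, from: n13, to: gastric_end}
terminal_labels:
  T7: Left Recurrent Laryngeal Nerve
  T9: Cardiac Plexus
  T16: Hepatic Plexus
  T18: Gastric Plexus
  T14: Splenic Nerve
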