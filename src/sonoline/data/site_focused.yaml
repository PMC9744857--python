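# Site-focused splenic stimulation topology (mirrors
# sonoline.network.site_focused_model): a strictly linear chain from the skin
# over the spleen down to the splenic nerve. Same dialect as cervical_vagus.yaml.
name: site_focused_splenic
source: transducer
lines:
  - {id: T1, tissue: epidermis, from: transducer, to: n1}
  - {id: T2, tissue: dermis, from: n1, to: n2}
  - {id: T3, tissue: subcutaneous_tissue, from: n2, to: n3}
  - {id: T4, tissue: intercostal_muscle, from: n3, to: n4}
  - {id: T5, tissue: diaphragm, from: n4, to: n5}
  - {id: T6, tissue: spleen_capsule, from: n5, to: n6}
  - {id: T7, tissue: spleen, from: n6, to: n7}
  - {id: T8, tissue: splenic_nerve, from: n7, to: splenic_end}
terminal_labels:
  T8: Splenic Nerve
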