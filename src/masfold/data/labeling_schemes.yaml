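# NMR-visible carbon sets per labeling scheme. These are simplified
# residue-type masks: true isotopomer statistics of glucose-based sparse
# labeling are out of scope. "default" applies to every residue type
# unless an explicit residue-type override is given; visibility is always
# intersected with the carbons the residue actually has.
uniform_13C:
  default: [CA, C, CB, CG, CD]
glucose_16:
  # 1,6-13C glucose: carbonyl- and outer-sidechain-dominated visibility,
  # thinned per residue type to emulate sparse-labeling contact density
  default: [C]
  LEU: [CD]
  ILE: [CD, C]
  PHE: [CD, C]
  LYS: [CD]
  GLU: [CD]
  ALA: [CB]
  THR: [CG]
  GLY: [C]
glucose_2:
  # 2-13C glucose: Calpha-dominated visibility
  default: [CA]
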