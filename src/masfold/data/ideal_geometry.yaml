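# Ideal covalent geometry for the reduced heavy-atom protein model.
# Bond lengths in Angstrom, angles/impropers in degrees, force constants
# in kcal/mol/A^2 (bonds) and kcal/mol/rad^2 (angles, impropers).
# Values follow standard Engh-Huber-style protein geometry; users may
# override by passing their own table to build_topology().
bonds:
  N-CA: 1.458
  CA-C: 1.525
  C-O: 1.231
  C-N: 1.329
  CA-CB: 1.530
  CB-CG: 1.530
  CG-CD: 1.530
angles:
  N-CA-C: 111.2
  CA-C-O: 120.8
  CA-C-N: 116.2
  O-C-N: 123.0
  C-N-CA: 121.7
  N-CA-CB: 110.5
  CA-CB-CG: 114.0
  CB-CG-CD: 114.0
impropers:
  # dihedral(N[i+1], CA, C, O): carbonyl planarity
  peptide_O: 180.0
  # dihedral(C, N, CA, CB): L-configuration of the beta branch
  CB_chirality: -122.6
force_constants:
  bond: 600.0
  angle: 80.0
  improper: 80.0
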