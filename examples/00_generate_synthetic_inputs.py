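"""Emit every input file the pipeline consumes, with known ground truth.

Generates the standard synthetic fixture and writes the file set a real
study would start from: the assigned peak list, the torsion-restraint table,
the true single-chain coordinates, the multi-copy lattice, the blurred
density map, and a ground-truth JSON (placements, contacts, seed).
"""

import masfold as mf
from masfold.synthetic import GroundTruth, make_fixture_a

fx = make_fixture_a()

mf.write_peaks_tsv(fx["peaks"], "peaks.tsv")
mf.write_torsions_tsv(fx["torsions"], "torsions.tsv")
mf.write_structure(fx["structure"], "truth.pdb")
mf.write_structure(fx["assembly"].to_structure(), "lattice.pdb")
mf.write_mrc(fx["map"], "map.mrc")
GroundTruth(structure=fx["structure"], placements=fx["placements"],
            contacts=fx["contacts"],
            seed=fx["params"]["seed"]).to_json("truth.json")

print(f"{len(fx['peaks'])} peaks -> peaks.tsv")
print(f"{len(fx['torsions'])} torsion restraints -> torsions.tsv")
print(f"single chain ({fx['structure'].n_residues} residues) -> truth.pdb")
print(f"{fx['assembly'].n_subunits}-copy lattice -> lattice.pdb")
print(f"map {fx['map'].shape} at {fx['map'].voxel_size} A/voxel -> map.mrc")
print("ground truth (placements, contacts, master seed) -> truth.json")
print("regenerating with the same parameters reproduces these files "
      "bit-exactly; the pipeline never reads the ground truth")
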