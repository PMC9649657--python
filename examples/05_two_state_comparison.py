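"""Chemical-shift-perturbation mapping between two sample states.

Simulates a second state in which a chosen set of residues is perturbed
(their resonances shift and their peaks attenuate — the signature of a
local conformational or dynamic change), then recovers exactly that set by
comparing the two peak lists.
"""

import masfold as mf

fx = mf.make_fixture_a()
peaks_apo = fx["peaks"]

perturbed = [4, 11, 25]  # the "planted" conformational change
peaks_bound, truth = mf.perturb_state(fx["structure"], peaks_apo, perturbed,
                                      shift_delta=0.4, intensity_factor=0.6,
                                      seed=2)
result = mf.compare_states(peaks_apo, peaks_bound,
                           csp_threshold=0.1, intensity_threshold=0.7)

table = result.residue_table
shifted = table[table["flag"] == "shifted"]
attenuated = table[table["flag"] == "attenuated"]
print(f"{len(result.deltas)} matched peaks; residues with shifted resonances:")
print(shifted.to_string(index=False))
print(f"planted perturbation: residues {truth.perturbed_residues}")
print(f"recovered (shifted):  residues {sorted(shifted['residue'])}")
print(f"additionally attenuated-only: {sorted(attenuated['residue'])} — "
      "intensity loss spreads to every residue sharing a cross-peak with a "
      "perturbed one, while the chemical-shift change localizes exactly")
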