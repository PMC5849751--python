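"""Classify lipid accessibility on a β-barrel and decompose its score.

Residues of an idealized 8-strand barrel alternate between pointing at the
lipid acyl chains and at the aqueous pore.  The classifier (side-chain
exposure plus an outward-ray occlusion test) recovers that split, and the
scoring engine reports how much of the total insertion score comes from
pore-facing (lipid-inaccessible) residues — the quantity the potential's
asymmetry analysis turns on.
"""

import numpy as np

import membpot as mp
from membpot import fixtures as fx

barrel = fx.build_ideal_barrel(n_strands=8)
result = mp.classify_residues(barrel)
truth = barrel.annotations["lipid_accessible_truth"]
agreement = np.mean(result.lipid_accessible == truth)
print(f"classifier vs construction ground truth: {agreement:.1%} agreement "
      f"({int(result.lipid_accessible.sum())} lipid-accessible of "
      f"{barrel.n_residues} residues)")

# score against a beta potential derived from a pore-enriched world:
# polar Ser favored in the pore, Leu at the lipid face
dists = fx.uniform_background(n_per_cell=2000)
dists[("S", False)] = [fx.Gaussian(12000, 0.0, 6.0)]
dists[("L", True)] = [fx.Gaussian(12000, 0.0, 6.0)]
models = fx.sample_structure_ensemble(
    fx.FixtureSpec(depth_distributions=dists, seed=11))
pset = mp.derive_potential(models, protein_class="beta")

pore_barrel = fx.build_ideal_barrel(n_strands=8, sequence="LSLSLSLSL")
mp.classify_residues(pore_barrel)
bd = mp.score_structure(pore_barrel, pset)
print(f"barrel score: total {bd.total:+.2f} = "
      f"lipid-accessible {bd.lipid_accessible_sum:+.2f} + "
      f"pore-facing {bd.lipid_inaccessible_sum:+.2f}")
print(f"pore-facing contribution: {bd.inaccessible_fraction:.1%} of the "
      "total — non-negligible, because pore-lining residues sit at "
      "membrane depth yet see water.")
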