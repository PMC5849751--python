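"""Derive an asymmetric implicit membrane potential from a synthetic world.

Builds a seeded residue ensemble in which every amino acid has a flat depth
background, accessible Lys is enriched on the inner leaflet (z < 0, the
positive-inside rule) and accessible Asp on the outer leaflet (the
charge-outside rule of bacterial outer membranes), then runs the full
derivation: 3 Å depth histograms, 3-bin smoothing, inverse-Boltzmann
inversion split by lipid accessibility, and functional-form fitting.
"""

import numpy as np

import membpot as mp
from membpot import fixtures as fx

dists = fx.uniform_background(n_per_cell=2000)
dists[("K", True)] = [fx.Gaussian(20000, -17.0, 4.0)]
dists[("D", True)] = [fx.Gaussian(20000, +17.0, 4.0)]
models = fx.sample_structure_ensemble(
    fx.FixtureSpec(depth_distributions=dists, seed=7))

pset = mp.derive_potential(models, protein_class="alpha")

z = np.array([-17.0, 0.0, +17.0, 30.0])
for aa in ("K", "D", "L"):
    prof = pset.profile(aa, accessible=True)
    vals = ", ".join(f"{v:+.2f}" for v in prof.evaluate(z))
    print(f"{aa} (accessible, {prof.fit.form:>15s}):  "
          f"E(z=-17, 0, +17, +30) = {vals}  kcal/mol")

mp.write_potential_table(pset, "alpha_potential.tsv")
print("\nFitted parameters written to alpha_potential.tsv.")
print("Negative values mark favorable depths: the Lys well sits on the "
      "inner leaflet and the Asp well on the outer leaflet, exactly the "
      "asymmetry the generating distributions stated; profiles approach "
      "zero in water (|z| > 24 Å).")
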