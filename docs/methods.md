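# Methods

This note records the model, the numerical choices and the limits of what
the test suite establishes.  It is the package's own account; all numbers
mentioned are computed by the tests or the acceptance script.

## Coordinate conventions

Structures are assumed pre-oriented in a membrane frame: normal along z,
bilayer center at z = 0, half-thickness 15 Å by default, and the
cytoplasmic/periplasmic ("inside") compartment at negative z.  This inner
/outer distinction is a fixed convention (`MembraneFrame.inner_leaflet_sign`)
and is never silently flipped; topology inversion is an explicit proper
180° rotation about x, (x, y, z) → (x, −y, −z), which preserves chirality
and is a bit-exact involution.  Embedding transforms rotate about x
through the protein's center of mass at its native position, then
translate along z — the rotation center is not specified by the usual
derivation protocols, and this choice keeps (dz = 0, tilt = 0) identical
to the native pose and makes dz read as the COM depth.  Multi-model (NMR)
files contribute only the model selected by `model_index` (default:
first).

## Derivation pipeline

1. **Counting.**  Each statistics-eligible residue (canonical amino acid,
   Cα present, not a hetero record, accessibility flag assigned)
   increments one cell of a 20 × 2 × 30 histogram: amino acid ×
   {lipid-accessible, lipid-inaccessible} × 3 Å bin over z ∈ [−45, 45] Å.
   The range covers the membrane plus interface; out-of-range residues go
   to a logged overflow tally and never enter fits.  Selenomethionine is
   counted as Met; other non-canonical residues are retained in models
   but excluded from statistics.
2. **Smoothing.**  A 3-bin sliding mean with edge-replication padding —
   the padding variant under which the per-profile total count is
   conserved exactly.
3. **Inversion.**  Within each accessibility class and bin,
   ΔG = kT ln(N / Σ_aa N) with kT = 0.593 kcal/mol (T = 298 K; the
   temperature is a config knob since derivations conventionally leave it
   implicit).  Zero cells in populated bins get a pseudocount of 0.5
   before the log; the denominator uses the adjusted counts, so the
   normalization Σ_aa exp(ΔG/kT) = 1 holds exactly per bin.  Bins empty
   across all amino acids are undefined and excluded from fitting.
4. **Referencing and sign.**  The literal log-frequency expression is
   non-positive everywhere, yet usable potentials must approach zero in
   water and make enrichment favorable.  Two explicit switches handle
   this.  `reference_mode="water_referenced"` (default) subtracts each
   profile's mean over |z| ≥ 24 Å.  `sign_convention="energy"` (the
   derivation default) negates the result, giving the conventional
   pseudo-energy −kT ln(frequency ratio) under which the lowest summed
   score marks the preferred topology/embedding; `"literal"` keeps the
   printed relation (used by the normalization test).  Both choices are
   recorded in the potential's provenance and table header.
5. **Fitting.**  Binned ΔG profiles are fitted by nonlinear least squares
   (scipy `curve_fit`, trf with width bounds d, g > 0.01, tolerances
   1e-14) with a double-Gaussian mixture, and by linear least squares
   with a 4th-order polynomial; the smaller sum of squared residuals
   wins, exact ties prefer the double Gaussian.  Starting values are
   histogram-derived: background = minimum (median for energy profiles),
   peak heights above it, peak positions from the extremes of each
   membrane half, widths ≈ one-eighth of the domain.  Raw count
   histograms can be fitted with single or double Gaussians the same way.
   Fitted forms are clamped to their boundary value outside the fitted
   z-domain (polynomials diverge).  Profiles with fewer than 8 defined
   bins or a raw total count below 200 are marked sparse and fall back to
   a flat water-reference value (zero when water-referenced); sparse
   amino acids (classically Cys) therefore contribute nothing to scores
   rather than noise.

## Lipid accessibility

The classifier approximates the published lipid-accessibility idea with
transparent geometry rather than cloning an external tool.  A residue is
lipid-accessible iff (a) its Cα lies within the membrane slab plus a 3 Å
interfacial margin (one bin; head-group contacts), (b) its relative
side-chain solvent exposure exceeds 0.20 — per-atom Shrake–Rupley SASA
with a 1.4 Å probe, summed over side-chain atoms and normalized by the
same atoms' SASA with the residue isolated, so the ratio is in [0, 1] for
any atom subset including Cα-only glycine proxies — and (c) a ray from
the side-chain centroid along the in-plane Cα→Cβ direction (virtual Cβ
for Gly, reconstructed from backbone geometry) clears all other atoms by
2.5 Å.  Occluders include the residue's own backbone, which is what
blocks pore-facing side chains in sparse fixture barrels exactly as
packed side chains would in real ones.  All thresholds are keyword
arguments; a table from an external classifier can be attached instead,
which is the route for reproducing published numbers faithfully.
Classification happens once on the native structure; flags ride along
with residues through rigid transforms, since burial is a
protein-internal property that rigid motion cannot change (and
re-classifying 1,476 grid cells would cost far more).

## Scoring applications

Only residues with |Cα z| ≤ 15 Å score.  The total is the sum of
per-residue fitted profile values; the decomposition into accessible and
inaccessible sums is exact by construction.  Topology prediction scores
the native and 180°-flipped poses; the strictly lower total wins, exact
ties call native with a tie flag, and both scores are always reported so
a margin can be applied downstream.  The embedding scan covers z ∈
[−100, 100] Å in 5 Å steps × tilt ∈ [0, 350°] in 10° steps (full-turn
coverage with simple indexing); the (0, 0) cell bypasses the rotation
arithmetic so it reproduces the native score bit-for-bit, and argmin ties
break toward smallest |z|, then smallest tilt.  ΔΔG of mutation is
E(mut) − E(wt) at the wild-type residue's depth and class — mutation does
not move the residue — giving ΔΔG(wt→wt) = 0 and antisymmetry exactly.

## Geometry

Secondary structure uses the Kabsch–Sander electrostatic hydrogen-bond
energy (0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, bond
below −0.5; amide H placed along the preceding C=O; prolines donate
nothing): helices are residues covered by two consecutive i → i+4 turns,
strands are residues in (anti)parallel bridge pairs.  No external
assigner binary is required.  A TM span is a maximal helix/strand run
whose terminal Cα z values satisfy z_first · z_last ≤ 0 — an endpoint
exactly on the center plane counts as crossing, so grazing spans are not
dropped — and runs longer than the membrane thickness are kept whole.
Span tilt is the angle between +z and the axis joining the unweighted
atom centers of the (i−1, i, i+1) triplets flanking the span ends
(terminal triplets, logged, when flanks are missing), folded to [0°, 90°].
The whole-protein tilt is the span-length-weighted mean of folded tilts;
on that folded half-range a circular mean is indistinguishable from the
arithmetic one for realistic spreads, so the arithmetic mean is used.

## Synthetic fixtures: what they are and are not

Ideal helices place Cα atoms on an exact cylinder (rise 1.5 Å, twist 100°
by default) and decorate them with N, C, O, Cβ offsets calibrated once
from an internal-coordinate (φ = −57.8°, ψ = −47.0°) reference helix, so
backbone hydrogen bonds register with the assigner while the stated
rise/twist stay exact.  Barrels place antiparallel strands on a cylinder
with alternating inward/outward Cβ and carry their construction-time
accessibility ground truth; the strand-pair fixture uses an empirically
calibrated antiparallel registration.  Sampled ensembles are Cα-only
pseudo-structures whose depths follow stated per-amino-acid distributions
(Gaussian or uniform components) with spec-provided accessibility flags —
they exercise the statistics path, not the geometric classifier.  Ensemble
defaults state the synthetic world used across tests and the acceptance
script: a flat background of 2,000 residues per amino acid per class over
±45 Å (enough to clear the sparse threshold in every 3 Å bin) with
enrichments of 20,000 residues, σ = 4 Å at |z| = 17 Å — an interfacial
charged-residue signal of the magnitude real leaflet asymmetries show.

A green test on these fixtures establishes that the machinery is correct:
conservation and normalization identities, recovery of known generating
distributions through the whole derive-and-fit loop, exact scoring
identities, and classifier agreement with an independent ray-casting
oracle on ideal barrels.  It does not establish database-level prediction
accuracy: fixtures have no rotamers, no loops between barrel strands, no
real side-chain packing and no experimental noise, and the published
database-scale numbers require the real oriented-structure databases plus
external experimental tables (see `examples/full_scale_pipeline.py`).

## Numerical notes and limitations

- Coordinates are stored in float32 (the container's native dtype);
  identities that depend on a recentered center of mass hold to ~1e-6,
  while flip involution, score decomposition and the native grid cell are
  exact.
- Curation rules are evaluated in a fixed order (resolution, R-factor,
  length, method, Cα-only, EM label) and the first violation is reported;
  missing resolution/R-factor fields skip their rule, since non-X-ray
  entries legitimately lack them.
- The span file writer emits the Rosetta dialect plus a trailing
  span-type token per line so round-trips are lossless; the reader
  accepts files without it.
- The geometric accessibility classifier is an approximation; near its
  thresholds (exposure ≈ 0.20, interfacial |z| ≈ 18 Å) it can disagree
  with the published tool it approximates, which is why the external
  table import exists.
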