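"""Lipid accessibility: is a residue facing the acyl chains or not?

Residues of a membrane-embedded protein are classified as lipid-accessible
(side chain contacting the hydrophobic lipid environment) or
lipid-inaccessible (buried in the protein core or facing an aqueous pore —
the operative distinction for asymmetric potential derivation, since
pore-facing residues of β-barrels are water-exposed despite sitting at
membrane depth).

The classifier is a documented geometric approximation of the published
Rosetta ``mp_lipid_acc`` idea, not a clone of it: a residue is
lipid-accessible iff

1. its Cα lies inside the membrane slab plus a small interfacial margin,
2. its relative side-chain solvent exposure (Shrake–Rupley, probe 1.4 Å)
   exceeds a threshold, and
3. a ray cast from the side-chain centroid along the outward in-plane
   Cα→Cβ direction escapes the protein body unoccluded.

All thresholds are keyword-exposed.  An externally produced classification
table can be imported instead via :func:`apply_external_classification`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc

from ._aa import BACKBONE_ATOMS
from .structure import MembraneFrame, StructureModel

logger = logging.getLogger(__name__)

#: coefficients of the standard virtual-Cβ reconstruction from N, Cα, C
_CB_COEFF = (-0.58273431, 0.56802827, -0.54067466)


def pseudo_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Idealized Cβ position from backbone geometry (used for Gly)."""
    b = ca - n
    cv = c - ca
    a = np.cross(b, cv)
    return _CB_COEFF[0] * a + _CB_COEFF[1] * b + _CB_COEFF[2] * cv + ca


@dataclass
class AccessibilityResult:
    """Per-residue accessibility flags and relative side-chain exposures."""

    lipid_accessible: np.ndarray      # bool, aligned with model.residues
    exposure: np.ndarray              # float in [0, 1]; NaN if not computed
    method_tag: str

    def to_frame(self, model: StructureModel) -> pd.DataFrame:
        return pd.DataFrame({
            "chain": [r.chain_id for r in model.residues],
            "residue": [r.residue_index for r in model.residues],
            "aa": [r.aa_type or r.res_name for r in model.residues],
            "lipid_accessible": self.lipid_accessible.astype(int),
            "exposure": self.exposure,
        })

    def write_table(self, model: StructureModel, path: str | Path) -> None:
        self.to_frame(model).to_csv(path, sep="\t", index=False)


def classify_residues(
    model: StructureModel,
    frame: MembraneFrame | None = None,
    *,
    exposure_threshold: float = 0.20,
    probe_radius: float = 1.4,
    slab_margin: float = 3.0,
    occlusion_radius: float = 2.5,
    min_ray_distance: float = 1.0,
    sasa_points: int = 300,
    attach: bool = True,
) -> AccessibilityResult:
    """Classify every residue of a full-atom model.

    ``slab_margin`` widens the membrane slab for the classification only
    (interfacial side chains still touch lipid headgroups); residues outside
    the widened slab are lipid-inaccessible by definition.  Deterministic:
    identical input yields identical flags.
    """
    frame = frame or model.frame
    atoms = model.atoms
    prot = model.protein_atom_mask()
    if not prot.any():
        raise ValueError("no protein atoms to classify")
    prot_atoms = atoms[prot]
    if np.all(prot_atoms.atom_name == "CA"):
        raise ValueError(
            "model is Cα-only: side-chain exposure cannot be computed; "
            "supply a full-atom structure or an external classification table"
        )

    atom_sasa = struc.sasa(prot_atoms, probe_radius=probe_radius,
                           vdw_radii="Single", point_number=sasa_points)
    atom_sasa = np.nan_to_num(atom_sasa)
    coords = np.asarray(prot_atoms.coord, dtype=float)

    # map residues of the model onto atom ranges of the protein subset
    starts = struc.get_residue_starts(prot_atoms, add_exclusive_stop=True)
    range_of: dict[tuple[str, int], tuple[int, int]] = {}
    for b, e in zip(starts[:-1], starts[1:]):
        range_of[(str(prot_atoms.chain_id[b]), int(prot_atoms.res_id[b]))] = (b, e)

    n_res = model.n_residues
    flags = np.zeros(n_res, dtype=bool)
    exposure = np.full(n_res, np.nan)

    for i, rec in enumerate(model.residues):
        if not rec.statistics_eligible:
            continue
        key = (rec.chain_id, rec.residue_index)
        if key not in range_of:
            continue
        b, e = range_of[key]
        names = prot_atoms.atom_name[b:e]
        side = ~np.isin(names, list(BACKBONE_ATOMS))
        if not side.any():
            side = names == "CA"   # Gly / sparse models: Cα as proxy
        sub_idx = np.arange(b, e)[side]

        # relative exposure: in-context SASA over the residue-alone SASA
        alone = struc.sasa(prot_atoms[b:e], probe_radius=probe_radius,
                           vdw_radii="Single", point_number=sasa_points)
        ref = float(np.nan_to_num(alone)[side].sum())
        ctx = float(atom_sasa[sub_idx].sum())
        exposure[i] = min(1.0, ctx / ref) if ref > 0 else 0.0

        z_ca = rec.ca_coord[2]
        in_slab = abs(z_ca - frame.center_z) <= frame.half_thickness + slab_margin
        if not in_slab or exposure[i] <= exposure_threshold:
            continue

        direction = _outward_direction(prot_atoms, b, e, rec)
        if direction is None:
            # not enough geometry for the ray test: exposure decides
            flags[i] = True
            continue
        origin = coords[sub_idx].mean(axis=0)
        occluders = np.ones(len(coords), dtype=bool)
        occluders[sub_idx] = False
        rel = coords[occluders] - origin
        t = rel @ direction
        ahead = t > min_ray_distance
        perp = np.linalg.norm(rel[ahead] - t[ahead, None] * direction, axis=1)
        flags[i] = not np.any(perp < occlusion_radius)

    if attach:
        for rec, f in zip(model.residues, flags):
            if rec.statistics_eligible:
                rec.lipid_accessible = bool(f)
    return AccessibilityResult(
        lipid_accessible=flags,
        exposure=exposure,
        method_tag=(f"sasa-ray/probe={probe_radius}/thr={exposure_threshold}/"
                    f"occ={occlusion_radius}"),
    )


def _outward_direction(prot_atoms, b: int, e: int, rec) -> np.ndarray | None:
    """Unit in-plane (xy) Cα→Cβ direction; pseudo-Cβ for Gly."""
    names = prot_atoms.atom_name[b:e]
    coords = np.asarray(prot_atoms.coord[b:e], dtype=float)

    def get(name):
        idx = np.flatnonzero(names == name)
        return coords[idx[0]] if len(idx) else None

    ca = get("CA")
    cb = get("CB")
    if cb is None:
        n, c = get("N"), get("C")
        if n is None or c is None or ca is None:
            return None
        cb = pseudo_cbeta(n, ca, c)
    vec = cb - ca
    vec[2] = 0.0
    norm = np.linalg.norm(vec)
    if norm < 1e-6:
        return None
    return vec / norm


def apply_external_classification(
    model: StructureModel, path: str | Path
) -> AccessibilityResult:
    """Attach flags from an externally produced table, bypassing the
    internal classifier (e.g. output of the original Rosetta tool exported
    in this module's tab-delimited layout: chain, residue,
    lipid_accessible, exposure)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chain", "residue", "lipid_accessible"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    table = {
        (str(row.chain), int(row.residue)): bool(row.lipid_accessible)
        for row in df.itertuples()
    }
    n_res = model.n_residues
    flags = np.zeros(n_res, dtype=bool)
    exposure = np.full(n_res, np.nan)
    if "exposure" in df.columns:
        exp_table = {
            (str(row.chain), int(row.residue)): float(row.exposure)
            for row in df.itertuples()
        }
    else:
        exp_table = {}
    for i, rec in enumerate(model.residues):
        key = (rec.chain_id, rec.residue_index)
        if key in table:
            flags[i] = table[key]
            exposure[i] = exp_table.get(key, np.nan)
            if rec.statistics_eligible:
                rec.lipid_accessible = flags[i]
        elif rec.statistics_eligible:
            logger.warning("no external classification for %s%d",
                           rec.chain_id, rec.residue_index)
    return AccessibilityResult(flags, exposure, method_tag=f"external:{path}")
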