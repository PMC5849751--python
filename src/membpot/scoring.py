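"""Scoring structures against an implicit membrane potential.

Applications: per-structure score decomposition into lipid-accessible and
lipid-inaccessible contributions, in/out topology prediction (native vs
180°-flipped, lower score wins), exhaustive depth × tilt embedding scans,
and ddG-of-mutation prediction at a site.

Only residues whose Cα lies inside the membrane slab contribute.
Accessibility flags are computed once on the native structure and carried
through rigid-body transforms: they encode protein-internal burial, which
rigid motion does not change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .potentials import PotentialSet
from .structure import (
    MembraneFrame,
    StructureModel,
    center_of_mass,
    flip_topology,
)

logger = logging.getLogger(__name__)


class ResidueScore(NamedTuple):
    chain_id: str
    residue_index: int
    aa: str
    accessibility: str
    z: float
    score: float


@dataclass
class ScoreBreakdown:
    """Total membrane-insertion score and its accessibility split."""

    total: float
    lipid_accessible_sum: float
    lipid_inaccessible_sum: float
    per_residue: list[ResidueScore]
    n_membrane_residues: int

    @property
    def inaccessible_fraction(self) -> float:
        """Contribution of lipid-inaccessible residues to the total score
        (the pore-facing/buried share)."""
        if self.total == 0:
            return float("nan")
        return self.lipid_inaccessible_sum / self.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_residue)


@dataclass
class TopologyPrediction:
    native_score: float
    inverted_score: float
    call: str                    # "native" | "inverted"
    tie_flag: bool = False


@dataclass
class EmbeddingGrid:
    """Score matrix over z-offsets × tilt angles around the native cell."""

    z_offsets: np.ndarray
    tilt_angles: np.ndarray
    scores: np.ndarray           # shape (len(z_offsets), len(tilt_angles))
    argmin: tuple[float, float]  # (z, tilt) of the minimum
    native_score: float

    def to_long_frame(self) -> pd.DataFrame:
        """Long format (z, tilt, score), suitable for heatmapping."""
        zz, tt = np.meshgrid(self.z_offsets, self.tilt_angles, indexing="ij")
        return pd.DataFrame({"z": zz.ravel(), "tilt": tt.ravel(),
                             "score": self.scores.ravel()})


@dataclass
class DDGPrediction:
    site: int
    wt_aa: str
    mut_aa: str
    z: float
    accessibility: str
    ddg: float


def _scoring_arrays(model: StructureModel):
    """(aa, accessible, z) arrays plus bookkeeping for eligible residues;
    raises if a flag is missing."""
    recs = [r for r in model.residues if r.statistics_eligible]
    for r in recs:
        if r.lipid_accessible is None:
            raise ValueError(
                f"residue {r.chain_id}{r.residue_index} has no lipid-"
                "accessibility flag; run classify_residues (or attach an "
                "external classification) before scoring"
            )
    aa = np.array([r.aa_type for r in recs])
    acc = np.array([bool(r.lipid_accessible) for r in recs])
    z = np.array([r.ca_coord[2] for r in recs])
    return recs, aa, acc, z


def score_structure(
    model: StructureModel,
    pset: PotentialSet,
    frame: MembraneFrame | None = None,
) -> ScoreBreakdown:
    """Sum fitted per-residue energies over membrane residues.

    The decomposition identity ``total = accessible_sum + inaccessible_sum``
    holds exactly (the two sums are computed from the same per-residue
    score vector).
    """
    frame = frame or model.frame
    recs, aa, acc, z = _scoring_arrays(model)
    mem = np.abs(z - frame.center_z) <= frame.half_thickness
    if not mem.any():
        return ScoreBreakdown(0.0, 0.0, 0.0, [], 0)
    scores = pset.evaluate_many(aa[mem], z[mem], acc[mem])
    acc_m = acc[mem]
    acc_sum = float(scores[acc_m].sum())
    inacc_sum = float(scores[~acc_m].sum())
    per_residue = [
        ResidueScore(r.chain_id, r.residue_index, r.aa_type,
                     "accessible" if a else "inaccessible", float(zz),
                     float(s))
        for r, a, zz, s in zip(
            [r for r, m in zip(recs, mem) if m], acc_m, z[mem], scores)
    ]
    return ScoreBreakdown(
        total=acc_sum + inacc_sum,
        lipid_accessible_sum=acc_sum,
        lipid_inaccessible_sum=inacc_sum,
        per_residue=per_residue,
        n_membrane_residues=int(mem.sum()),
    )


def predict_topology(
    model: StructureModel,
    pset: PotentialSet,
    frame: MembraneFrame | None = None,
) -> TopologyPrediction:
    """Score the model and its 180°-flipped topology; lower score wins.

    An exact tie keeps the native call with ``tie_flag`` set.  Both scores
    are reported so any downstream margin can be applied.
    """
    frame = frame or model.frame
    native = score_structure(model, pset, frame).total
    inverted = score_structure(flip_topology(model), pset, frame).total
    if native == inverted:
        return TopologyPrediction(native, inverted, "native", tie_flag=True)
    call = "native" if native < inverted else "inverted"
    return TopologyPrediction(native, inverted, call)


def embedding_scan(
    model: StructureModel,
    pset: PotentialSet,
    frame: MembraneFrame | None = None,
    z_step: float = 5.0,
    tilt_step: float = 10.0,
    z_max: float = 100.0,
    tilt_max: float = 350.0,
) -> EmbeddingGrid:
    """Exhaustive rigid-body embedding scan.

    The protein is rotated about x through its native center of mass and
    translated along the membrane normal over z in [-z_max, z_max] (default
    5 Å steps) × tilt in [0, tilt_max] (default 10° steps, covering the full
    turn).  Cell (z=0, tilt=0) reproduces the native score exactly.
    Accessibility flags travel with the residues.  The reported minimum
    breaks ties toward the smallest |z|, then the smallest tilt.
    """
    frame = frame or model.frame
    _, aa, acc, z_native = _scoring_arrays(model)
    com_z = center_of_mass(model)[2]
    # y relative to COM is needed for the rotation about x
    recs = [r for r in model.residues if r.statistics_eligible]
    y_rel = np.array([r.ca_coord[1] for r in recs]) - center_of_mass(model)[1]
    z_rel = z_native - com_z
    z_offsets = np.arange(-z_max, z_max + z_step / 2, z_step)
    tilt_angles = np.arange(0.0, tilt_max + tilt_step / 2, tilt_step)
    scores = np.empty((len(z_offsets), len(tilt_angles)))
    for it, tilt in enumerate(tilt_angles):
        if tilt == 0.0:
            z_rot = z_native            # bit-exact native cell
        else:
            rad = np.deg2rad(tilt)
            z_rot = np.sin(rad) * y_rel + np.cos(rad) * z_rel + com_z
        for iz, dz in enumerate(z_offsets):
            z = z_rot + dz
            mem = np.abs(z - frame.center_z) <= frame.half_thickness
            if not mem.any():
                scores[iz, it] = 0.0
                continue
            vals = pset.evaluate_many(aa[mem], z[mem], acc[mem])
            scores[iz, it] = float(vals[acc[mem]].sum()) + float(
                vals[~acc[mem]].sum())
    best = scores.min()
    cand = np.argwhere(scores == best)
    order = sorted(
        (abs(z_offsets[iz]), tilt_angles[it], iz, it) for iz, it in cand)
    _, _, iz, it = order[0]
    iz0 = int(np.argmin(np.abs(z_offsets)))
    return EmbeddingGrid(
        z_offsets=z_offsets,
        tilt_angles=tilt_angles,
        scores=scores,
        argmin=(float(z_offsets[iz]), float(tilt_angles[it])),
        native_score=float(scores[iz0, 0]),
    )


def predict_ddg(
    model: StructureModel,
    site: int,
    mut_aa: str,
    pset: PotentialSet,
    frame: MembraneFrame | None = None,
    chain_id: str | None = None,
) -> DDGPrediction:
    """ddG of mutating ``site`` to ``mut_aa``: E(mut) - E(wt) at the
    wild-type residue's depth and accessibility class (the mutation does
    not move the residue)."""
    frame = frame or model.frame
    matches = [r for r in model.residues
               if r.residue_index == site
               and (chain_id is None or r.chain_id == chain_id)]
    if not matches:
        raise KeyError(f"no residue {site} in model")
    rec = matches[0]
    if not rec.statistics_eligible or rec.lipid_accessible is None:
        raise ValueError(f"residue {site} lacks coordinates or an "
                         "accessibility flag")
    z = float(rec.ca_coord[2])
    if abs(z - frame.center_z) > frame.half_thickness:
        logger.warning("site %d is outside the membrane (z = %.1f); ddG uses "
                       "clamped profile values", site, z)
    acc = bool(rec.lipid_accessible)
    ddg = float(pset.evaluate(mut_aa, z, acc) - pset.evaluate(rec.aa_type, z, acc))
    return DDGPrediction(
        site=site, wt_aa=rec.aa_type, mut_aa=mut_aa, z=z,
        accessibility="accessible" if acc else "inaccessible", ddg=ddg,
    )
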