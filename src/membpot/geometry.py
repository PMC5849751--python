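"""Secondary structure, transmembrane span detection, lengths and tilts.

Secondary structure uses the Kabsch–Sander hydrogen-bond energy criterion
(the DSSP model): an electrostatic bond energy below -0.5 kcal/mol between
a backbone N-H donor and C=O acceptor defines an H-bond; helices are runs
of consecutive i+4 turns and strands are residues in (anti)parallel bridge
ladders.  This internal assigner keeps the package self-contained; fixture
models also carry construction-time labels which any caller may prefer.

A transmembrane span is a maximal helix/strand segment whose first and last
Cα lie on opposite sides of the membrane center plane (an endpoint exactly
at z = 0 counts as spanning); segments longer than the membrane is thick
are kept whole.  Span tilt is the angle between the membrane normal and the
axis through the centers of mass of the three-residue windows flanking the
span ends, folded to [0°, 90°].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure import MembraneFrame, SpanRecord, StructureModel

logger = logging.getLogger(__name__)

_HB_CUTOFF = -0.5          # kcal/mol, Kabsch-Sander threshold
_HB_FACTOR = 0.084 * 332.0


@dataclass
class TMSpanStats:
    span: SpanRecord
    length: int            # residues
    tilt: float            # degrees in [0, 90]


def _backbone_arrays(model: StructureModel):
    """Per-residue backbone coordinates (NaN where atoms are missing)."""
    atoms = model.atoms
    n_res = model.n_residues
    out = {name: np.full((n_res, 3), np.nan) for name in ("N", "CA", "C", "O")}
    key_to_idx = {(r.chain_id, r.residue_index): i
                  for i, r in enumerate(model.residues)}
    for j in range(atoms.array_length()):
        name = atoms.atom_name[j]
        if name in out:
            key = (str(atoms.chain_id[j]), int(atoms.res_id[j]))
            i = key_to_idx.get(key)
            if i is not None and np.isnan(out[name][i, 0]):
                out[name][i] = atoms.coord[j]
    return out


def _hbond_matrix(model: StructureModel) -> np.ndarray:
    """hbond[i, j]: backbone N-H of residue i donates to C=O of residue j."""
    bb = _backbone_arrays(model)
    n = model.n_residues
    chains = np.array([r.chain_id for r in model.residues])
    is_pro = np.array([r.aa_type == "P" for r in model.residues])
    # amide H along the previous peptide's C=O direction (DSSP convention)
    h = np.full((n, 3), np.nan)
    for i in range(1, n):
        if chains[i] != chains[i - 1]:
            continue
        co = bb["C"][i - 1] - bb["O"][i - 1]
        norm = np.linalg.norm(co)
        if np.isfinite(norm) and norm > 0:
            h[i] = bb["N"][i] + co / norm
    donor_ok = np.isfinite(h[:, 0]) & np.isfinite(bb["N"][:, 0]) & ~is_pro
    acceptor_ok = np.isfinite(bb["C"][:, 0]) & np.isfinite(bb["O"][:, 0])
    hbond = np.zeros((n, n), dtype=bool)
    # distance prefilter on Cα pairs keeps the pair loop small
    ca = bb["CA"]
    ca_ok = np.isfinite(ca[:, 0])
    for i in np.flatnonzero(donor_ok & ca_ok):
        d2 = np.sum((ca - ca[i]) ** 2, axis=1)
        for j in np.flatnonzero(acceptor_ok & ca_ok & (d2 < 81.0)):
            if abs(i - j) < 2 and chains[i] == chains[j]:
                continue
            r_on = np.linalg.norm(bb["O"][j] - bb["N"][i])
            r_ch = np.linalg.norm(bb["C"][j] - h[i])
            r_oh = np.linalg.norm(bb["O"][j] - h[i])
            r_cn = np.linalg.norm(bb["C"][j] - bb["N"][i])
            if min(r_on, r_oh) < 0.5:       # clash guard
                continue
            energy = _HB_FACTOR * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if energy < _HB_CUTOFF:
                hbond[i, j] = True
    return hbond


def assign_secondary_structure(
    model: StructureModel, attach: bool = True
) -> np.ndarray:
    """Per-residue class: helix / strand / coil / unassigned.

    Helix: residues covered by two consecutive i -> i+4 turns.  Strand:
    residues in parallel or antiparallel bridge pairs.  Residues lacking
    backbone atoms are unassigned.  With ``attach`` the labels are written
    onto the model's residues.
    """
    n = model.n_residues
    bb = _backbone_arrays(model)
    complete = np.all(
        [np.isfinite(bb[name][:, 0]) for name in ("N", "CA", "C", "O")],
        axis=0)
    hbond = _hbond_matrix(model)
    turn4 = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        if hbond[i + 4, i]:
            turn4[i] = True
    ss = np.array(["coil"] * n, dtype=object)
    for i in range(1, n - 4):
        if turn4[i - 1] and turn4[i]:
            ss[i:i + 4] = "helix"
    for i in range(1, n - 1):
        for j in range(i + 2, n - 1):
            anti = (hbond[i, j] and hbond[j, i]) or (
                hbond[i - 1, j + 1] and hbond[j - 1, i + 1])
            para = (hbond[i, j - 1] and hbond[j + 1, i]) or (
                hbond[j, i - 1] and hbond[i + 1, j])
            if anti or para:
                for k in (i, j):
                    if ss[k] != "helix":
                        ss[k] = "strand"
    ss[~complete] = "unassigned"
    if attach:
        for rec, label in zip(model.residues, ss):
            rec.ss_class = str(label)
    return ss.astype(str)


def detect_tm_spans(
    model: StructureModel,
    frame: MembraneFrame | None = None,
    min_length: int = 3,
) -> list[SpanRecord]:
    """Maximal helix/strand segments crossing the membrane center plane.

    Uses the residues' current ``ss_class`` labels (run
    :func:`assign_secondary_structure` first, or rely on fixture ground
    truth).  A segment spans if its terminal Cα z values satisfy
    z_first * z_last <= 0, so an endpoint exactly on the center plane
    counts.  Detection is idempotent.
    """
    frame = frame or model.frame
    spans: list[SpanRecord] = []
    runs: list[tuple[str, list[int]]] = []
    for i, rec in enumerate(model.residues):
        label = rec.ss_class
        if label in ("helix", "strand"):
            if runs and runs[-1][0] == label and _consecutive(model, runs[-1][1][-1], i):
                runs[-1][1].append(i)
            else:
                runs.append((label, [i]))
    for label, members in runs:
        with_ca = [i for i in members if model.residues[i].ca_coord is not None]
        if len(members) < min_length or len(with_ca) < 2:
            continue
        z_first = model.residues[with_ca[0]].ca_coord[2] - frame.center_z
        z_last = model.residues[with_ca[-1]].ca_coord[2] - frame.center_z
        if z_first * z_last <= 0:
            spans.append(SpanRecord(
                start_residue=model.residues[members[0]].residue_index,
                end_residue=model.residues[members[-1]].residue_index,
                span_type=label,
            ))
    return spans


def _consecutive(model: StructureModel, i: int, j: int) -> bool:
    a, b = model.residues[i], model.residues[j]
    return (a.chain_id == b.chain_id and j == i + 1
            and b.residue_index == a.residue_index + 1)


def _triplet_com(model: StructureModel, positions: list[int]) -> np.ndarray:
    """Unweighted center of the atoms of the given residues (Cα fallback)."""
    atoms = model.atoms
    keys = {(model.residues[p].chain_id, model.residues[p].residue_index)
            for p in positions}
    sel = np.array([
        (str(atoms.chain_id[k]), int(atoms.res_id[k])) in keys
        for k in range(atoms.array_length())])
    if sel.any():
        return np.asarray(atoms.coord, dtype=float)[sel].mean(axis=0)
    cas = [model.residues[p].ca_coord for p in positions
           if model.residues[p].ca_coord is not None]
    return np.mean(cas, axis=0)


def compute_span_tilt(model: StructureModel, span: SpanRecord) -> float:
    """Tilt of a TM span versus the membrane normal, in degrees [0, 90].

    The span axis runs between the centers of mass of the residue triplets
    (i-1, i, i+1) around the start and end residues; when flanking residues
    are missing the span's own terminal triplets are used (logged)."""
    idx = {r.residue_index: i for i, r in enumerate(model.residues)}
    try:
        s, e = idx[span.start_residue], idx[span.end_residue]
    except KeyError as err:
        raise KeyError(f"span residue missing from model: {err}") from None
    chain = model.residues[s].chain_id

    def window(center: int, inward: int) -> list[int]:
        pos = [center - 1, center, center + 1]
        if (pos[0] < 0 or pos[-1] >= model.n_residues
                or model.residues[pos[0]].chain_id != chain
                or model.residues[pos[-1]].chain_id != chain):
            logger.info("span %d-%d lacks flanking residues; using terminal "
                        "triplet", span.start_residue, span.end_residue)
            pos = sorted({center, center + inward, center + 2 * inward})
            pos = [p for p in pos if 0 <= p < model.n_residues]
        return pos

    com_start = _triplet_com(model, window(s, +1))
    com_end = _triplet_com(model, window(e, -1))
    axis = com_end - com_start
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("degenerate span: zero-length axis")
    raw = np.degrees(np.arccos(np.clip(axis[2] / norm, -1.0, 1.0)))
    return float(min(raw, 180.0 - raw))


def span_axis_angle(model: StructureModel, span: SpanRecord) -> float:
    """Unfolded axis angle versus +z in [0°, 180°) (orientation-aware)."""
    idx = {r.residue_index: i for i, r in enumerate(model.residues)}
    s, e = idx[span.start_residue], idx[span.end_residue]
    com_start = _triplet_com(model, [max(s - 1, 0), s, s + 1])
    com_end = _triplet_com(model, [e - 1, e, min(e + 1, model.n_residues - 1)])
    axis = com_end - com_start
    return float(np.degrees(np.arccos(
        np.clip(axis[2] / np.linalg.norm(axis), -1.0, 1.0))))


def compute_span_stats(
    model: StructureModel, frame: MembraneFrame | None = None
) -> list[TMSpanStats]:
    spans = detect_tm_spans(model, frame)
    return [
        TMSpanStats(span=sp,
                    length=sp.end_residue - sp.start_residue + 1,
                    tilt=compute_span_tilt(model, sp))
        for sp in spans
    ]


def whole_protein_tilt(
    model: StructureModel, frame: MembraneFrame | None = None
) -> float:
    """Length-weighted mean of the folded span tilts (degrees)."""
    stats = compute_span_stats(model, frame)
    if not stats:
        raise ValueError("no transmembrane spans detected")
    weights = np.array([s.length for s in stats], dtype=float)
    tilts = np.array([s.tilt for s in stats])
    return float(np.sum(weights * tilts) / weights.sum())


def span_length_histogram(
    stats: list[TMSpanStats], bin_width: int = 1
) -> pd.DataFrame:
    """Span-length histogram (default one-residue bins)."""
    if not stats:
        return pd.DataFrame(columns=["bin_center", "count"])
    lengths = np.array([s.length for s in stats])
    lo = (lengths.min() // bin_width) * bin_width
    hi = lengths.max() + bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(lengths, bins=edges)
    centers = edges[:-1] + (bin_width - 1) / 2.0 if bin_width > 1 else edges[:-1]
    return pd.DataFrame({"bin_center": centers.astype(float),
                         "count": counts})


def tilt_histogram(
    stats: list[TMSpanStats], bin_width: float = 5.0
) -> pd.DataFrame:
    """Tilt-angle histogram over [0°, 90°] (default 5° bins)."""
    if not stats:
        return pd.DataFrame(columns=["bin_center", "count"])
    tilts = np.array([s.tilt for s in stats])
    edges = np.arange(0.0, 90.0 + bin_width, bin_width)
    counts, _ = np.histogram(tilts, bins=edges)
    return pd.DataFrame({"bin_center": edges[:-1] + bin_width / 2.0,
                         "count": counts})
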