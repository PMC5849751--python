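"""Membrane-oriented protein structures and rigid-body operations.

Structures are assumed to be pre-oriented in a membrane frame following the
PDBTM/OPM convention: the membrane normal is the z-axis, the bilayer center
is at z = 0, and the cytoplasmic/periplasmic ("inside") compartment lies at
negative z.  All coordinates are in Ångström.

The module provides reading and cleaning of PDB files, the 180° topology
flip, depth/tilt rigid-body transforms used by embedding scans, and the
Rosetta span-file dialect.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from ._aa import (
    MODIFIED_TO_CANONICAL,
    THREE_TO_ONE,
    WATER_NAMES,
)

logger = logging.getLogger(__name__)

SS_CLASSES = ("helix", "strand", "coil", "unassigned")


@dataclass(frozen=True)
class MembraneFrame:
    """Implicit membrane slab: normal along z, centered at ``center_z``.

    ``inner_leaflet_sign`` records the fixed convention that negative z is
    the cytoplasmic/periplasmic side; it is never flipped by any operation.
    """

    center_z: float = 0.0
    half_thickness: float = 15.0
    inner_leaflet_sign: int = -1

    def __post_init__(self) -> None:
        if self.half_thickness <= 0:
            raise ValueError("half_thickness must be positive")
        if self.inner_leaflet_sign != -1:
            raise ValueError("inner leaflet at negative z is a fixed convention")

    def in_membrane(self, z: np.ndarray | float) -> np.ndarray | bool:
        return np.abs(np.asarray(z) - self.center_z) <= self.half_thickness


@dataclass
class ResidueRecord:
    """One residue of a membrane-oriented model.

    ``aa_type`` is the canonical one-letter code or ``None`` for
    non-canonical residues (which are kept in the model but excluded from
    statistics).  ``ca_coord`` is ``None`` when the residue lacks a Cα.
    """

    chain_id: str
    residue_index: int
    res_name: str
    aa_type: str | None
    ca_coord: np.ndarray | None
    ss_class: str = "unassigned"
    lipid_accessible: bool | None = None
    is_hetero: bool = False

    @property
    def statistics_eligible(self) -> bool:
        return (
            self.aa_type is not None
            and self.ca_coord is not None
            and not self.is_hetero
        )


@dataclass
class SpanRecord:
    """A transmembrane span between two residue positions (inclusive)."""

    start_residue: int
    end_residue: int
    span_type: str = "helix"

    def __post_init__(self) -> None:
        if self.start_residue >= self.end_residue:
            raise ValueError("span start must precede span end")
        if self.span_type not in ("helix", "strand"):
            raise ValueError(f"unknown span type {self.span_type!r}")


@dataclass
class StructureModel:
    """A membrane-oriented protein with per-residue annotations.

    ``atoms`` holds the full coordinate set (used for SASA / secondary
    structure); ``residues`` is the ordered residue-level view used by the
    statistics and scoring paths.  The two stay coordinate-consistent: every
    rigid-body operation in this module transforms both.
    """

    atoms: struc.AtomArray
    residues: list[ResidueRecord]
    frame: MembraneFrame = field(default_factory=MembraneFrame)
    topology_label: str = "native"
    source_id: str = ""
    annotations: dict = field(default_factory=dict)

    def copy(self) -> "StructureModel":
        return StructureModel(
            atoms=self.atoms.copy(),
            residues=[
                replace(r, ca_coord=None if r.ca_coord is None else r.ca_coord.copy())
                for r in self.residues
            ],
            frame=self.frame,
            topology_label=self.topology_label,
            source_id=self.source_id,
            annotations=copy.deepcopy(self.annotations),
        )

    # -- residue-level convenience views -------------------------------
    def ca_z(self) -> np.ndarray:
        """Cα z for every residue (NaN where the Cα is missing)."""
        out = np.full(len(self.residues), np.nan)
        for i, r in enumerate(self.residues):
            if r.ca_coord is not None:
                out[i] = r.ca_coord[2]
        return out

    def eligible_mask(self) -> np.ndarray:
        return np.array([r.statistics_eligible for r in self.residues], dtype=bool)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def protein_atom_mask(self) -> np.ndarray:
        return ~self.atoms.hetero | np.isin(
            self.atoms.res_name, list(MODIFIED_TO_CANONICAL)
        )


def _canonical_aa(res_name: str) -> str | None:
    if res_name in THREE_TO_ONE:
        return THREE_TO_ONE[res_name]
    return MODIFIED_TO_CANONICAL.get(res_name)


def model_from_atoms(
    atoms: struc.AtomArray,
    frame: MembraneFrame | None = None,
    source_id: str = "",
) -> StructureModel:
    """Build a :class:`StructureModel` from a biotite ``AtomArray``."""
    frame = frame or MembraneFrame()
    residues: list[ResidueRecord] = []
    starts = struc.get_residue_starts(atoms, add_exclusive_stop=True)
    for begin, end in zip(starts[:-1], starts[1:]):
        res_name = atoms.res_name[begin]
        is_water = res_name in WATER_NAMES
        is_hetero = bool(atoms.hetero[begin]) and res_name not in MODIFIED_TO_CANONICAL
        aa = _canonical_aa(res_name)
        ca_sel = np.flatnonzero(atoms.atom_name[begin:end] == "CA")
        ca = atoms.coord[begin + ca_sel[0]].copy() if len(ca_sel) else None
        if aa is not None and ca is None and not is_hetero:
            logger.warning(
                "residue %s %s%d lacks a CA atom; excluded from statistics",
                res_name, atoms.chain_id[begin], int(atoms.res_id[begin]),
            )
        residues.append(
            ResidueRecord(
                chain_id=str(atoms.chain_id[begin]),
                residue_index=int(atoms.res_id[begin]),
                res_name=str(res_name),
                aa_type=aa,
                ca_coord=ca,
                is_hetero=is_hetero or is_water,
            )
        )
    return StructureModel(atoms=atoms, residues=residues, frame=frame,
                          source_id=source_id)


def read_structure(
    path: str | Path,
    model_index: int = 1,
    frame: MembraneFrame | None = None,
) -> StructureModel:
    """Read a membrane-oriented PDB file into a :class:`StructureModel`.

    Coordinates are taken verbatim: the file must already be oriented in the
    membrane frame (z normal, center at z = 0).  Multi-model files (NMR
    ensembles) contribute a single model, ``model_index`` (1-based,
    default: first).
    """
    path = Path(path)
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=model_index)
    return model_from_atoms(atoms, frame=frame, source_id=path.stem)


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write the model's atoms as a standard PDB file."""
    pdb = PDBFile()
    pdb.set_structure(model.atoms)
    pdb.write(str(path))


def clean_structure(model: StructureModel) -> StructureModel:
    """Remove ligands, co-factors, waters and other hetero records.

    Protein residues (including selenomethionine) are untouched.  Returns a
    new model; the input is not modified.
    """
    keep_res = [r for r in model.residues if not r.is_hetero]
    if not keep_res:
        logger.warning("structure %s contains no protein residues after cleaning",
                       model.source_id)
    keep_atoms = model.protein_atom_mask()
    water = np.isin(model.atoms.res_name, list(WATER_NAMES))
    out = model.copy()
    out.atoms = out.atoms[keep_atoms & ~water]
    out.residues = [
        replace(r, ca_coord=None if r.ca_coord is None else r.ca_coord.copy())
        for r in keep_res
    ]
    return out


def _apply_to_coords(model: StructureModel, fn) -> StructureModel:
    out = model.copy()
    out.atoms.coord = fn(np.asarray(out.atoms.coord, dtype=float))
    for r in out.residues:
        if r.ca_coord is not None:
            r.ca_coord = fn(r.ca_coord[None, :])[0]
    return out


def flip_topology(model: StructureModel) -> StructureModel:
    """180° rotation about the x-axis: (x, y, z) -> (x, -y, -z).

    A proper rotation (chirality preserved), used to invert the in/out
    topology of a membrane-embedded structure.  Applying it twice restores
    every coordinate bit-for-bit.  Per-residue annotations (accessibility,
    secondary structure) travel with their residues.
    """

    def fn(c: np.ndarray) -> np.ndarray:
        c = c.copy()
        c[:, 1] = -c[:, 1]
        c[:, 2] = -c[:, 2]
        return c

    out = _apply_to_coords(model, fn)
    out.topology_label = "inverted" if model.topology_label == "native" else "native"
    return out


def center_of_mass(model: StructureModel) -> np.ndarray:
    """Unweighted centroid of the protein (non-hetero) atoms."""
    mask = model.protein_atom_mask()
    if not mask.any():
        mask = np.ones(model.atoms.array_length(), dtype=bool)
    return np.asarray(model.atoms.coord, dtype=float)[mask].mean(axis=0)


def rotation_about_x(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def transform_embedding(
    model: StructureModel, dz: float, tilt: float
) -> StructureModel:
    """Rigid-body re-embedding: tilt about x through the COM, then shift z.

    The rotation center is the protein's center of mass at its current
    (native) position, so ``dz`` reads as the membrane depth of the rotated
    protein's COM and (dz=0, tilt=0) is the identity.
    """
    com = center_of_mass(model)
    rot = rotation_about_x(tilt)
    shift = np.array([0.0, 0.0, dz])

    def fn(c: np.ndarray) -> np.ndarray:
        if tilt == 0.0:
            return c + shift
        return (c - com) @ rot.T + com + shift

    return _apply_to_coords(model, fn)


# ---------------------------------------------------------------------------
# Rosetta span files
# ---------------------------------------------------------------------------

def write_span_file(
    model: StructureModel, spans: Sequence[SpanRecord], path: str | Path
) -> None:
    """Write spans in the Rosetta span-file dialect.

    Header: a free-text line, then "<n_spans> <sequence_length>", then the
    ``antiparallel`` / ``n2c`` convention lines, then one line per span with
    the start/end residue numbers (written twice, as Rosetta does) plus the
    span type as a trailing token (this writer's extension; the reader
    defaults to helix when absent).
    """
    n_res = len(model.residues)
    indices = {r.residue_index for r in model.residues}
    for s in spans:
        if s.start_residue not in indices or s.end_residue not in indices:
            raise ValueError(
                f"span {s.start_residue}-{s.end_residue} outside the model"
            )
    lines = [
        f"TM span file for {model.source_id or 'model'}",
        f"{len(spans)} {n_res}",
        "antiparallel",
        "n2c",
    ]
    for s in spans:
        lines.append(
            f"{s.start_residue:>6d} {s.end_residue:>6d}"
            f" {s.start_residue:>6d} {s.end_residue:>6d} {s.span_type}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_span_file(path: str | Path) -> tuple[list[SpanRecord], int]:
    """Read a Rosetta span file; returns (spans, sequence_length)."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 2:
        raise ValueError(f"{path}: truncated span file (line 2 missing)")
    try:
        n_spans, n_res = (int(tok) for tok in lines[1].split()[:2])
    except (ValueError, IndexError) as err:
        raise ValueError(f"{path}: line 2: expected '<n_spans> <length>'") from err
    spans: list[SpanRecord] = []
    body = [ln for ln in lines[2:] if ln.strip() and ln.split()[0] not in (
        "antiparallel", "parallel", "n2c", "c2n")]
    if len(body) < n_spans:
        raise ValueError(f"{path}: declared {n_spans} spans, found {len(body)}")
    for i, ln in enumerate(body[:n_spans]):
        toks = ln.split()
        try:
            start, end = int(toks[0]), int(toks[1])
        except (ValueError, IndexError) as err:
            raise ValueError(f"{path}: line {i + 5}: malformed span line") from err
        span_type = "helix"
        if toks and toks[-1] in ("helix", "strand"):
            span_type = toks[-1]
        if end > n_res:
            raise ValueError(
                f"{path}: line {i + 5}: span end {end} exceeds length {n_res}"
            )
        spans.append(SpanRecord(start, end, span_type))
    return spans, n_res
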