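"""Chain-level dataset curation for potential derivation.

Applies the standard structure-quality filters (resolution better than 3 Å,
R-factor below 0.3, 40-10,000 residues, no Cα-only or electron-microscopy
entries; non-X-ray entries allowed) to a manifest of candidate chains and
assembles the cleaned, topology-normalized derivation set.  Sequence-
similarity redundancy culling is assumed to have happened upstream: the
manifest lists already-culled chains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .structure import StructureModel, clean_structure, flip_topology, read_structure

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = [
    "pdb_id", "chain", "flip_flag", "protein_class",
    "resolution", "r_factor", "length", "method", "ca_only",
]


@dataclass(frozen=True)
class ChainMetadata:
    """Quality metadata of one candidate chain.

    ``resolution``/``r_factor`` may be None (e.g. NMR entries); rules that
    need a missing field are skipped rather than failed.  ``label`` is the
    free-text experiment record, checked for EM markers.
    """

    pdb_id: str
    chain: str
    length: int
    method: str = "xray"              # xray | nmr | em | other
    resolution: float | None = None
    r_factor: float | None = None
    ca_only: bool = False
    label: str = ""

    def __post_init__(self):
        if self.length < 0:
            raise ValueError("length must be non-negative")
        if self.resolution is not None and self.resolution < 0:
            raise ValueError("resolution must be non-negative")


@dataclass(frozen=True)
class CurationCriteria:
    max_resolution: float = 3.0
    max_r_factor: float = 0.3
    min_length: int = 40
    max_length: int = 10000
    allow_non_xray: bool = True
    exclude_ca_only: bool = True
    exclude_em: bool = True

    def __post_init__(self):
        if self.min_length >= self.max_length:
            raise ValueError("min_length must be below max_length")


def _first_violation(meta: ChainMetadata, c: CurationCriteria) -> str | None:
    if meta.resolution is not None and meta.resolution > c.max_resolution:
        return "resolution"
    if meta.r_factor is not None and meta.r_factor > c.max_r_factor:
        return "r_factor"
    if meta.length < c.min_length:
        return "length_min"
    if meta.length > c.max_length:
        return "length_max"
    if not c.allow_non_xray and meta.method != "xray":
        return "method"
    if c.exclude_ca_only and meta.ca_only:
        return "ca_only"
    if c.exclude_em and (meta.method == "em"
                         or "EM" in meta.label.upper().split()
                         or "ELEC" in meta.label.upper()):
        return "electron_microscopy"
    return None


def apply_curation(
    chains: Sequence[ChainMetadata],
    criteria: CurationCriteria | None = None,
) -> tuple[list[ChainMetadata], list[tuple[ChainMetadata, str]]]:
    """Partition chains into (kept, rejected-with-first-violated-rule).

    Deterministic and order-preserving: every input chain lands in exactly
    one of the two outputs, in input order.
    """
    criteria = criteria or CurationCriteria()
    kept: list[ChainMetadata] = []
    rejected: list[tuple[ChainMetadata, str]] = []
    for meta in chains:
        reason = _first_violation(meta, criteria)
        if reason is None:
            kept.append(meta)
        else:
            rejected.append((meta, reason))
    return kept, rejected


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the tab-delimited chain manifest.

    Required columns: pdb_id, chain, flip_flag (0/1: flip to match the
    reference in/out topology), protein_class (alpha/beta); the
    ChainMetadata fields (resolution, r_factor, length, method, ca_only)
    are optional but recommended.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"pdb_id", "chain", "flip_flag", "protein_class"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    return df


def manifest_metadata(df: pd.DataFrame) -> list[ChainMetadata]:
    """ChainMetadata records from manifest rows (NaN -> None)."""
    out = []
    for row in df.itertuples():
        res = getattr(row, "resolution", None)
        rfac = getattr(row, "r_factor", None)
        out.append(ChainMetadata(
            pdb_id=str(row.pdb_id),
            chain=str(row.chain),
            length=int(getattr(row, "length", 0)),
            method=str(getattr(row, "method", "xray")),
            resolution=None if pd.isna(res) else float(res),
            r_factor=None if pd.isna(rfac) else float(rfac),
            ca_only=str(getattr(row, "ca_only", "False")).lower()
            in ("1", "true", "yes"),
            label=str(getattr(row, "label", "") or ""),
        ))
    return out


def assemble_dataset(
    manifest_path: str | Path,
    structure_dir: str | Path,
    protein_class: str,
) -> list[StructureModel]:
    """Load, clean and topology-normalize every manifest chain of a class.

    Structures are expected as ``<structure_dir>/<pdb_id>.pdb`` in the
    membrane frame.  Chains flagged ``flip_flag`` are rotated 180° about x
    to match the reference topology.  Missing files are skipped with a
    warning; an empty result is a hard error.
    """
    if protein_class not in ("alpha", "beta"):
        raise ValueError("protein_class must be 'alpha' or 'beta'")
    df = read_manifest(manifest_path)
    df = df[df["protein_class"] == protein_class]
    structure_dir = Path(structure_dir)
    models: list[StructureModel] = []
    for row in df.itertuples():
        path = structure_dir / f"{row.pdb_id}.pdb"
        if not path.exists():
            logger.warning("structure file missing, skipping: %s", path)
            continue
        model = clean_structure(read_structure(path))
        if int(row.flip_flag):
            model = flip_topology(model)
        model.annotations["protein_class"] = protein_class
        model.annotations["manifest_chain"] = str(row.chain)
        models.append(model)
    if not models:
        raise ValueError(
            f"no structures loaded for class {protein_class!r} from "
            f"{manifest_path}"
        )
    return models
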