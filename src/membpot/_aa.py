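"""Amino acid constants shared across modules."""

from __future__ import annotations

# Canonical ordering used for histogram / potential indexing.
AA_ORDER: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA_ORDER)}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

# Modified residues mapped onto a canonical parent for statistics.
# Selenomethionine is the only mapping adopted; everything else
# non-canonical is retained in models but excluded from statistics.
MODIFIED_TO_CANONICAL: dict[str, str] = {"MSE": "M"}

# Atom names treated as backbone (everything else is side chain).
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HA"})

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

# Accessibility class labels, in fixed index order.
ACCESSIBILITY_CLASSES: tuple[str, str] = ("accessible", "inaccessible")
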