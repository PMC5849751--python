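"""Derivation of depth-dependent implicit membrane potentials.

The pipeline: count Cα occurrences of each amino acid per 3 Å depth bin,
split by lipid accessibility; smooth with a 3-bin sliding window; invert to
pseudo-free energies with the inverse Boltzmann relation

    dG(aa, bin) = kT * ln( N(aa, bin) / sum_aa' N(aa', bin) ),

normalizing within each accessibility class; and fit each per-amino-acid
profile with a double-Gaussian mixture or, where that fits worse, a
4th-order polynomial.  Raw total-count histograms can also be fit with
single/double Gaussians.

Because the literal inverse Boltzmann expression is a log of a fraction and
therefore non-positive everywhere, the default ``water_referenced`` mode
subtracts each amino acid's mean energy in the aqueous region (|z| beyond
``z_ref``), so profiles approach zero in water and may cross zero in the
membrane; ``raw`` mode keeps the literal values.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ._aa import AA_INDEX, AA_ORDER, ACCESSIBILITY_CLASSES
from .structure import StructureModel

logger = logging.getLogger(__name__)

KT_298 = 0.593  # kcal/mol at T = 298 K

FORMS = ("single_gaussian", "double_gaussian", "poly4")
PARAM_NAMES = {
    "single_gaussian": ("a", "b", "c", "d"),
    "double_gaussian": ("a", "b", "c", "d", "e", "f", "g"),
    "poly4": ("a", "b", "c", "d", "e"),
}


class FitError(RuntimeError):
    """Nonlinear fit failure, carrying the starting values used."""

    def __init__(self, message: str, start_params: Sequence[float]):
        super().__init__(f"{message} (start parameters: {list(start_params)})")
        self.start_params = list(start_params)


def single_gaussian(z, a, b, c, d):
    return a + b * np.exp(-((z - c) ** 2) / (2 * d ** 2))


def double_gaussian(z, a, b, c, d, e, f, g):
    return (a + b * np.exp(-((z - c) ** 2) / (2 * d ** 2))
            + e * np.exp(-((z - f) ** 2) / (2 * g ** 2)))


def poly4(z, a, b, c, d, e):
    return np.polyval([a, b, c, d, e], z)


_FORM_FN = {"single_gaussian": single_gaussian,
            "double_gaussian": double_gaussian,
            "poly4": poly4}


@dataclass
class FitModel:
    """A fitted functional form over a z-domain, clamped outside it."""

    form: str
    params: np.ndarray
    residual: float                 # sum of squared deviations at the data
    z_range: tuple[float, float]

    def __post_init__(self):
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}")
        self.params = np.asarray(self.params, dtype=float)
        if len(self.params) != len(PARAM_NAMES[self.form]):
            raise ValueError(f"{self.form} needs "
                             f"{len(PARAM_NAMES[self.form])} parameters")

    @property
    def params_dict(self) -> dict[str, float]:
        return dict(zip(PARAM_NAMES[self.form], self.params))

    def evaluate(self, z) -> np.ndarray | float:
        """Evaluate at z, clamped to the boundary value beyond z_range
        (polynomials diverge otherwise)."""
        zc = np.clip(np.asarray(z, dtype=float), *self.z_range)
        out = _FORM_FN[self.form](zc, *self.params)
        return float(out) if np.isscalar(z) else out


@dataclass
class CountHistogram:
    """Amino acid × accessibility class × z-bin occupancy counts."""

    bin_edges: np.ndarray                  # (n_bins + 1,)
    counts: np.ndarray                     # (20, 2, n_bins)
    overflow: np.ndarray                   # (20, 2) out-of-range tallies
    n_structures: int = 0
    smoothed: np.ndarray | None = None     # same shape as counts

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def effective_counts(self) -> np.ndarray:
        return self.counts if self.smoothed is None else self.smoothed

    def to_frame(self) -> pd.DataFrame:
        """Long-format dump: aa, class, bin_center, raw, smoothed."""
        rows = []
        sm = self.smoothed
        for ai, aa in enumerate(AA_ORDER):
            for ci, cls in enumerate(ACCESSIBILITY_CLASSES):
                for bi, center in enumerate(self.bin_centers):
                    rows.append((aa, cls, center, self.counts[ai, ci, bi],
                                 np.nan if sm is None else sm[ai, ci, bi]))
        return pd.DataFrame(rows,
                            columns=["aa", "class", "bin_center", "raw",
                                     "smoothed"])


def accumulate_histograms(
    models: Iterable[StructureModel],
    bin_width: float = 3.0,
    z_range: tuple[float, float] = (-45.0, 45.0),
) -> CountHistogram:
    """Count eligible residues into (aa, accessibility, z-bin) cells.

    A residue is eligible if it is a canonical amino acid with a Cα and an
    accessibility flag.  Residues outside ``z_range`` are tallied in a
    logged overflow counter and excluded from fitting.  Raises if a model
    contains eligible residues that were never classified.
    """
    lo, hi = z_range
    n_bins = int(round((hi - lo) / bin_width))
    if not math.isclose(lo + n_bins * bin_width, hi):
        raise ValueError("z_range must be an integer number of bins")
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts = np.zeros((len(AA_ORDER), 2, n_bins))
    overflow = np.zeros((len(AA_ORDER), 2))
    n_structures = 0
    for model in models:
        n_structures += 1
        for rec in model.residues:
            if not rec.statistics_eligible:
                continue
            if rec.lipid_accessible is None:
                raise ValueError(
                    f"residue {rec.chain_id}{rec.residue_index} of "
                    f"{model.source_id!r} has no lipid-accessibility flag; "
                    "run classify_residues first"
                )
            ai = AA_INDEX[rec.aa_type]
            ci = 0 if rec.lipid_accessible else 1
            z = rec.ca_coord[2]
            bi = int(np.floor((z - lo) / bin_width))
            if 0 <= bi < n_bins:
                counts[ai, ci, bi] += 1
            else:
                overflow[ai, ci] += 1
    if overflow.sum():
        logger.info("%d residues outside the histogram range (overflow bin)",
                    int(overflow.sum()))
    if n_structures == 0:
        raise ValueError("no structures supplied")
    return CountHistogram(bin_edges=edges, counts=counts, overflow=overflow,
                          n_structures=n_structures)


def smooth_window3(hist: CountHistogram) -> CountHistogram:
    """3-bin sliding mean over each (aa, class) histogram.

    Edges use replicated padding (the edge bin stands in for its missing
    neighbor), the policy under which the total count is conserved exactly.
    """
    if hist.n_bins < 3:
        raise ValueError("need at least 3 bins to smooth")
    padded = np.pad(hist.counts, ((0, 0), (0, 0), (1, 1)), mode="edge")
    smoothed = (padded[:, :, :-2] + padded[:, :, 1:-1] + padded[:, :, 2:]) / 3.0
    return replace(hist, smoothed=smoothed)


@dataclass
class EnergyProfile:
    """Depth-dependent pseudo-energy of one amino acid in one class."""

    aa: str
    accessibility: str                  # "accessible" | "inaccessible"
    bin_centers: np.ndarray
    dg: np.ndarray                      # kcal/mol; NaN where undefined
    kT: float
    fit: FitModel | None = None
    sparse: bool = False
    flat_value: float = 0.0             # fallback when sparse / unfit
    total_count: float = 0.0

    @property
    def z_range(self) -> tuple[float, float]:
        if self.fit is not None:
            return self.fit.z_range
        defined = np.isfinite(self.dg)
        if not defined.any():
            return (0.0, 0.0)
        centers = self.bin_centers[defined]
        return (float(centers.min()), float(centers.max()))

    def evaluate(self, z) -> np.ndarray | float:
        if self.sparse:
            out = np.full_like(np.asarray(z, dtype=float), self.flat_value)
            return float(self.flat_value) if np.isscalar(z) else out
        if self.fit is not None:
            return self.fit.evaluate(z)
        defined = np.isfinite(self.dg)
        if not defined.any():
            out = np.full_like(np.asarray(z, dtype=float), self.flat_value)
            return float(self.flat_value) if np.isscalar(z) else out
        centers = self.bin_centers[defined]
        vals = self.dg[defined]
        out = np.interp(np.asarray(z, dtype=float), centers, vals)
        return float(out) if np.isscalar(z) else out


def counts_to_free_energy(
    hist: CountHistogram,
    kT: float = KT_298,
    reference_mode: str = "water_referenced",
    z_ref: float = 24.0,
    pseudocount: float = 0.5,
    sparse_threshold: float = 200.0,
    sign_convention: str = "literal",
) -> list[EnergyProfile]:
    """Invert (smoothed) counts to per-amino-acid energy profiles.

    Within each accessibility class and bin, dG = kT ln(N / sum_aa N); zero
    cells in a populated bin receive ``pseudocount`` before the log (the
    denominator uses the adjusted counts, so sum_aa exp(dG/kT) = 1 holds
    exactly in raw mode).  Bins with no counts at all are undefined (NaN).
    Profiles whose raw total count falls below ``sparse_threshold`` are
    marked sparse and fall back to their flat water-reference value.

    ``sign_convention``: the literal log-frequency relation assigns
    enriched amino acids *higher* (less negative) values; for a potential
    where enrichment is energetically favorable — the convention under
    which the lowest summed score marks the preferred topology and
    embedding — set ``"energy"``, which negates the profiles
    (dG = -kT ln(...), i.e. the usual inverse-Boltzmann pseudo-energy).
    """
    if reference_mode not in ("raw", "water_referenced"):
        raise ValueError(f"unknown reference_mode {reference_mode!r}")
    if sign_convention not in ("literal", "energy"):
        raise ValueError(f"unknown sign_convention {sign_convention!r}")
    counts = hist.effective_counts()
    centers = hist.bin_centers
    water = np.abs(centers) >= z_ref
    profiles: list[EnergyProfile] = []
    for ci, cls in enumerate(ACCESSIBILITY_CLASSES):
        block = counts[:, ci, :]                       # (20, n_bins)
        bin_total = block.sum(axis=0)                  # per-bin totals
        adjusted = np.where(block == 0, pseudocount, block)
        adjusted = np.where(bin_total[None, :] > 0, adjusted, np.nan)
        denom = np.nansum(adjusted, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            dg = kT * np.log(adjusted / denom[None, :])
        for ai, aa in enumerate(AA_ORDER):
            vals = dg[ai].copy()
            defined = np.isfinite(vals)
            water_defined = defined & water
            offset = float(np.mean(vals[water_defined])) if water_defined.any() else 0.0
            if reference_mode == "water_referenced":
                vals = vals - offset
                flat = 0.0
            else:
                flat = offset
            if sign_convention == "energy":
                vals = -vals
                flat = -flat
            total = float(hist.counts[ai, ci, :].sum())
            profiles.append(EnergyProfile(
                aa=aa, accessibility=cls, bin_centers=centers.copy(),
                dg=vals, kT=kT, sparse=total < sparse_threshold,
                flat_value=flat, total_count=total,
            ))
            if total < sparse_threshold:
                logger.info("sparse profile: %s/%s has %d counts "
                            "(< %g); flat fallback", aa, cls, int(total),
                            sparse_threshold)
    return profiles


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _gaussian_starts(z: np.ndarray, y: np.ndarray, form: str) -> list[float]:
    """Histogram-derived starting values: a = background, b/e = peak heights
    above it, c/f = peak centers, d/g = peak standard deviations."""
    a0 = float(np.min(y))
    dev = y - a0
    if form == "single_gaussian":
        i = int(np.argmax(dev))
        width = max((z.max() - z.min()) / 6.0, 1.0)
        return [a0, float(dev[i]), float(z[i]), width]
    # double: one peak per membrane half
    width = max((z.max() - z.min()) / 8.0, 1.0)
    left = z < np.median(z)
    right = ~left
    il = int(np.argmax(np.where(left, dev, -np.inf)))
    ir = int(np.argmax(np.where(right, dev, -np.inf)))
    return [a0, float(dev[il]), float(z[il]), width,
            float(dev[ir]), float(z[ir]), width]


def _curve_fit(form: str, z: np.ndarray, y: np.ndarray,
               p0: Sequence[float]) -> FitModel:
    fn = _FORM_FN[form]
    names = PARAM_NAMES[form]
    lower = [-np.inf] * len(names)
    upper = [np.inf] * len(names)
    for i, nm in enumerate(names):
        if form.endswith("gaussian") and nm in ("d", "g"):
            lower[i] = 1e-2          # widths strictly positive
    p0 = [max(p, 1e-2) if form.endswith("gaussian") and nm in ("d", "g") else p
          for p, nm in zip(p0, names)]
    try:
        popt, _ = curve_fit(fn, z, y, p0=p0, bounds=(lower, upper),
                            maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    except (RuntimeError, ValueError) as err:
        raise FitError(f"{form} fit did not converge: {err}", p0) from err
    residual = float(np.sum((fn(z, *popt) - y) ** 2))
    return FitModel(form=form, params=popt, residual=residual,
                    z_range=(float(z.min()), float(z.max())))


def fit_counts(
    bin_centers: np.ndarray,
    values: np.ndarray,
    form: str = "single_gaussian",
) -> FitModel:
    """Fit a raw count histogram with a single or double Gaussian."""
    if form not in ("single_gaussian", "double_gaussian"):
        raise ValueError("fit_counts handles Gaussian forms only")
    z = np.asarray(bin_centers, dtype=float)
    y = np.asarray(values, dtype=float)
    good = np.isfinite(y)
    z, y = z[good], y[good]
    if len(z) < len(PARAM_NAMES[form]):
        raise FitError(f"only {len(z)} defined bins for {form}", [])
    return _curve_fit(form, z, y, _gaussian_starts(z, y, form))


def fit_energy_profile(
    bin_centers: np.ndarray,
    dg: np.ndarray,
    min_bins: int = 8,
) -> FitModel | None:
    """Fit binned dG with a double Gaussian and a 4th-order polynomial.

    The form with the smaller sum of squared residuals wins; exact ties
    prefer the double Gaussian.  Returns None (caller falls back to binned
    interpolation) when fewer than ``min_bins`` bins are defined or both
    fits fail.
    """
    z = np.asarray(bin_centers, dtype=float)
    y = np.asarray(dg, dtype=float)
    good = np.isfinite(y)
    z, y = z[good], y[good]
    if len(z) < min_bins:
        return None
    candidates: list[FitModel] = []
    # energy wells are negative peaks: seed with the deepest deviations
    a0 = float(np.median(y))
    dev = y - a0
    i_min, i_max = int(np.argmin(dev)), int(np.argmax(dev))
    starts = [
        [a0, float(dev[i_min]), float(z[i_min]), 6.0,
         float(dev[i_max]), float(z[i_max]), 6.0],
        _gaussian_starts(z, y, "double_gaussian"),
    ]
    for p0 in starts:
        try:
            candidates.append(_curve_fit("double_gaussian", z, y, p0))
            break
        except FitError:
            continue
    coeffs = np.polyfit(z, y, deg=4)
    residual = float(np.sum((np.polyval(coeffs, z) - y) ** 2))
    candidates.append(FitModel(form="poly4", params=coeffs, residual=residual,
                               z_range=(float(z.min()), float(z.max()))))
    if not candidates:
        return None
    return select_fit(candidates)


def select_fit(candidates: Sequence[FitModel]) -> FitModel:
    """Pick the candidate with the smallest residual; exact ties prefer the
    double Gaussian over the polynomial."""
    _PREFERENCE = {"double_gaussian": 0, "single_gaussian": 1, "poly4": 2}
    return min(candidates,
               key=lambda f: (f.residual, _PREFERENCE[f.form]))


# ---------------------------------------------------------------------------
# Potential sets
# ---------------------------------------------------------------------------

@dataclass
class PotentialSet:
    """Fitted energy profiles for 20 amino acids × two accessibility
    classes, with derivation metadata."""

    protein_class: str                      # "alpha" | "beta"
    kT: float
    reference_mode: str
    profiles: dict[tuple[str, str], EnergyProfile] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.protein_class not in ("alpha", "beta"):
            raise ValueError("protein_class must be 'alpha' or 'beta'")

    def profile(self, aa: str, accessible: bool) -> EnergyProfile:
        cls = ACCESSIBILITY_CLASSES[0 if accessible else 1]
        try:
            return self.profiles[(aa, cls)]
        except KeyError:
            raise KeyError(f"no profile for amino acid {aa!r} ({cls})") from None

    def evaluate(self, aa: str, z, accessible: bool = True):
        """Fitted potential of one amino acid at depth z (kcal/mol)."""
        return self.profile(aa, accessible).evaluate(z)

    def evaluate_many(self, aa: Sequence[str], z: np.ndarray,
                      accessible: np.ndarray) -> np.ndarray:
        """Vectorized evaluation for mixed amino acids/classes."""
        aa = np.asarray(aa)
        z = np.asarray(z, dtype=float)
        accessible = np.asarray(accessible, dtype=bool)
        out = np.empty(len(z))
        for aa_type in np.unique(aa):
            for acc in (True, False):
                mask = (aa == aa_type) & (accessible == acc)
                if mask.any():
                    out[mask] = self.profile(str(aa_type), acc).evaluate(z[mask])
        return out

    @property
    def sparse_amino_acids(self) -> list[tuple[str, str]]:
        return [key for key, p in self.profiles.items() if p.sparse]


def derive_potential(
    models: Iterable[StructureModel],
    protein_class: str = "alpha",
    bin_width: float = 3.0,
    z_range: tuple[float, float] = (-45.0, 45.0),
    kT: float = KT_298,
    reference_mode: str = "water_referenced",
    z_ref: float = 24.0,
    pseudocount: float = 0.5,
    sparse_threshold: float = 200.0,
    smooth: bool = True,
    sign_convention: str = "energy",
) -> PotentialSet:
    """End-to-end derivation: histograms -> smoothing -> inversion -> fits.

    Defaults to the ``energy`` sign convention (enrichment is favorable /
    negative), so summed scores are minimized by native-like topologies and
    embeddings; see :func:`counts_to_free_energy`.
    """
    hist = accumulate_histograms(models, bin_width=bin_width, z_range=z_range)
    if smooth:
        hist = smooth_window3(hist)
    profiles = counts_to_free_energy(
        hist, kT=kT, reference_mode=reference_mode, z_ref=z_ref,
        pseudocount=pseudocount, sparse_threshold=sparse_threshold,
        sign_convention=sign_convention)
    pset = PotentialSet(
        protein_class=protein_class, kT=kT, reference_mode=reference_mode,
        provenance={
            "n_structures": hist.n_structures,
            "bin_width": bin_width,
            "z_range": list(z_range),
            "z_ref": z_ref,
            "pseudocount": pseudocount,
            "sparse_threshold": sparse_threshold,
            "sign_convention": sign_convention,
            "smoothed": smooth,
            "dataset_hash": _counts_hash(hist),
        },
    )
    for prof in profiles:
        if not prof.sparse:
            prof.fit = fit_energy_profile(prof.bin_centers, prof.dg)
            if prof.fit is None:
                prof.sparse = True     # too few defined bins: flat fallback
                logger.info("profile %s/%s unfittable; flat fallback",
                            prof.aa, prof.accessibility)
        pset.profiles[(prof.aa, prof.accessibility)] = prof
    return pset


def _counts_hash(hist: CountHistogram) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(hist.counts).tobytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Parameter tables
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = [
    "protein_class", "aa", "accessibility", "form",
    "a", "b", "c", "d", "e", "f", "g",
    "residual", "z_min", "z_max", "sparse", "flat_value", "total_count",
]


def write_potential_table(pset: PotentialSet, path: str | Path) -> None:
    """Serialize fitted parameters as a tab-delimited table (mirrors the
    layout of published fit-parameter supplementary tables)."""
    rows = []
    for (aa, cls), prof in sorted(pset.profiles.items()):
        row = {c: "" for c in _TABLE_COLUMNS}
        row.update(protein_class=pset.protein_class, aa=aa, accessibility=cls,
                   sparse=int(prof.sparse), flat_value=prof.flat_value,
                   total_count=prof.total_count)
        if prof.sparse or prof.fit is None:
            row.update(form="flat", residual=0.0,
                       z_min=prof.z_range[0], z_max=prof.z_range[1])
        else:
            fit = prof.fit
            row.update(form=fit.form, residual=fit.residual,
                       z_min=fit.z_range[0], z_max=fit.z_range[1])
            row.update(fit.params_dict)
        rows.append(row)
    header = [
        "# membpot potential table",
        f"# protein_class: {pset.protein_class}",
        f"# kT: {pset.kT!r}",
        f"# reference_mode: {pset.reference_mode}",
    ]
    body = pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(
        sep="\t", index=False)
    Path(path).write_text("\n".join(header) + "\n" + body)


def read_potential_table(path: str | Path) -> PotentialSet:
    """Load a potential table (this layout also accepts third-party
    parameter tables written in the same columns).

    Missing amino-acid rows are marked sparse with a flat-zero fallback and
    a warning; malformed numeric fields raise with the row number.
    """
    path = Path(path)
    meta = {"protein_class": "alpha", "kT": KT_298,
            "reference_mode": "water_referenced"}
    lines = path.read_text().splitlines()
    n_header = 0
    for ln in lines:
        if not ln.startswith("#"):
            break
        n_header += 1
        if ":" in ln:
            key, _, val = ln.lstrip("# ").partition(":")
            key = key.strip()
            if key == "kT":
                meta["kT"] = float(val)
            elif key in meta:
                meta[key] = val.strip()
    df = pd.read_csv(path, sep="\t", skiprows=n_header)
    missing = {"aa", "accessibility", "form"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    pset = PotentialSet(protein_class=str(meta["protein_class"]),
                        kT=float(meta["kT"]),
                        reference_mode=str(meta["reference_mode"]),
                        provenance={"source_table": str(path)})
    for i, row in df.iterrows():
        rownum = i + n_header + 2
        aa = str(row["aa"])
        cls = str(row["accessibility"])
        if aa not in AA_INDEX or cls not in ACCESSIBILITY_CLASSES:
            raise ValueError(f"{path}: row {rownum}: unknown aa/class "
                             f"{aa!r}/{cls!r}")
        form = str(row["form"])
        try:
            flat = float(row.get("flat_value", 0.0) or 0.0)
            sparse = bool(int(row.get("sparse", 0) or 0))
            total = float(row.get("total_count", 0.0) or 0.0)
            if form == "flat":
                fit = None
                sparse = True
            elif form in FORMS:
                params = [float(row[nm]) for nm in PARAM_NAMES[form]]
                fit = FitModel(form=form, params=np.array(params),
                               residual=float(row.get("residual", 0.0) or 0.0),
                               z_range=(float(row["z_min"]),
                                        float(row["z_max"])))
            else:
                raise ValueError(f"{path}: row {rownum}: unknown form {form!r}")
        except (TypeError, ValueError) as err:
            if "unknown form" in str(err):
                raise
            raise ValueError(
                f"{path}: row {rownum}: malformed numeric field: {err}"
            ) from err
        pset.profiles[(aa, cls)] = EnergyProfile(
            aa=aa, accessibility=cls,
            bin_centers=np.array([]), dg=np.array([]),
            kT=pset.kT, fit=fit, sparse=sparse, flat_value=flat,
            total_count=total,
        )
    for aa in AA_ORDER:
        for cls in ACCESSIBILITY_CLASSES:
            if (aa, cls) not in pset.profiles:
                logger.warning("%s: no row for %s/%s; marked sparse "
                               "(flat zero)", path, aa, cls)
                pset.profiles[(aa, cls)] = EnergyProfile(
                    aa=aa, accessibility=cls, bin_centers=np.array([]),
                    dg=np.array([]), kT=pset.kT, sparse=True, flat_value=0.0)
    return pset
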