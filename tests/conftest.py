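"""Shared fixtures: synthetic structures, derived and toy potentials."""

from __future__ import annotations

import numpy as np
import pytest

import membpot as mp
from membpot import fixtures as fx
from membpot.potentials import EnergyProfile, FitModel, PotentialSet
from membpot._aa import AA_ORDER, ACCESSIBILITY_CLASSES

HELIX_SEQ = "LAIVALLAIVALLAIVALLAV"      # 21 residues, spans the membrane


@pytest.fixture(scope="session")
def helix():
    return fx.build_ideal_helix(HELIX_SEQ)


@pytest.fixture(scope="session")
def classified_helix():
    model = fx.build_ideal_helix(HELIX_SEQ)
    mp.classify_residues(model)
    return model


@pytest.fixture(scope="session")
def barrel():
    return fx.build_ideal_barrel(n_strands=8)


@pytest.fixture(scope="session")
def derived_pset():
    """Alpha potential derived from a seeded ensemble: flat background for
    every amino acid plus an inner-leaflet accessible-Lys enrichment."""
    dists = fx.uniform_background(n_per_cell=2000)
    dists[("K", True)] = [fx.Gaussian(20000, -17.0, 4.0),
                          fx.Uniform(2000, -45.0, 45.0)]
    models = fx.sample_structure_ensemble(
        fx.FixtureSpec(depth_distributions=dists, seed=20260918))
    return mp.derive_potential(models, protein_class="alpha")


def make_toy_pset(special: dict | None = None, protein_class="alpha",
                  z_range=(-45.0, 45.0)) -> PotentialSet:
    """Potential with flat-zero profiles except for explicit FitModels.

    ``special`` maps (aa, "accessible"|"inaccessible") -> FitModel.
    """
    special = special or {}
    pset = PotentialSet(protein_class=protein_class, kT=0.593,
                        reference_mode="water_referenced")
    for aa in AA_ORDER:
        for cls in ACCESSIBILITY_CLASSES:
            fit = special.get((aa, cls))
            if fit is None:
                fit = FitModel(form="poly4",
                               params=np.zeros(5), residual=0.0,
                               z_range=z_range)
            pset.profiles[(aa, cls)] = EnergyProfile(
                aa=aa, accessibility=cls,
                bin_centers=np.array([]), dg=np.array([]),
                kT=0.593, fit=fit)
    return pset


@pytest.fixture(scope="session")
def toy_pset():
    return make_toy_pset()


def format_pdb_atom(serial, name, resname, chain, resseq, x, y, z,
                    element=None, record="ATOM", hetero=False):
    """One fixed-column PDB coordinate line."""
    rec = "HETATM" if hetero else record
    element = element or name[0]
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (f"{rec:<6s}{serial:>5d} {name_field:<4s} {resname:>3s} "
            f"{chain}{resseq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}")


def write_pdb(path, lines):
    path.write_text("\n".join(lines + ["END"]) + "\n")
    return path
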