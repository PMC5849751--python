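"""Score decomposition, topology calls, embedding scans, ddG."""

import numpy as np
import pytest

import membpot as mp
from membpot import fixtures as fx
from membpot.potentials import FitModel, double_gaussian, single_gaussian

from conftest import make_toy_pset

# Hairpin whose up-helix carries a Lys early (low z) and whose down-helix
# carries a Lys late (also low z): a "positive-inside" ring near z = -12.
SEQ_UP = "LAKALALALALALALALALAL"
SEQ_DOWN = "LALALALALALALALALAKAL"


@pytest.fixture(scope="module")
def hairpin():
    model = fx.build_helix_hairpin(SEQ_UP, SEQ_DOWN)
    mp.classify_residues(model)
    return model


@pytest.fixture(scope="module")
def inside_positive_pset():
    """Toy alpha potential: accessible Lys favorable at the inner leaflet
    (well at z = -12), everything else flat zero."""
    well = FitModel("double_gaussian", [0.0, -2.0, -12.0, 3.0, 0.0, 12.0, 3.0],
                    residual=0.0, z_range=(-45.0, 45.0))
    return make_toy_pset({("K", "accessible"): well})


class TestScoreStructure:
    def test_everything_outside_membrane_scores_zero(self, toy_pset):
        model = fx.build_ideal_helix("LALALALALAL", embedding=(60.0, 0.0))
        mp.classify_residues(model)
        bd = mp.score_structure(model, toy_pset)
        assert bd.total == 0.0 and bd.n_membrane_residues == 0

    def test_decomposition_identity(self, hairpin, inside_positive_pset):
        bd = mp.score_structure(hairpin, inside_positive_pset)
        assert bd.total == bd.lipid_accessible_sum + bd.lipid_inaccessible_sum
        assert bd.total == pytest.approx(
            sum(r.score for r in bd.per_residue), abs=1e-12)
        assert all(abs(r.z) <= 15.0 for r in bd.per_residue)

    def test_two_residue_additivity(self, inside_positive_pset):
        dists = {("K", True): [fx.Gaussian(1, -12.0, 1e-9)],
                 ("L", True): [fx.Gaussian(1, 3.0, 1e-9)]}
        (model,) = fx.sample_structure_ensemble(
            fx.FixtureSpec(depth_distributions=dists, seed=2))
        bd = mp.score_structure(model, inside_positive_pset)
        assert len(bd.per_residue) == 2
        assert bd.total == pytest.approx(sum(r.score for r in bd.per_residue))

    def test_unclassified_model_is_error(self, toy_pset):
        model = fx.build_ideal_helix("LALAL")
        with pytest.raises(ValueError, match="classify"):
            mp.score_structure(model, toy_pset)


class TestTopology:
    def test_positive_inside_hairpin_prefers_native(
            self, hairpin, inside_positive_pset):
        """The Lys ring near the inner interface decides the call; the
        expected scores are re-derived by hand from the Gaussian well."""
        pred = mp.predict_topology(hairpin, inside_positive_pset)
        assert pred.call == "native" and not pred.tie_flag
        # hand-computed expectation: only the (accessible) Lys residues of
        # the membrane region score; all other profiles are flat zero
        k_res = [r for r in hairpin.residues
                 if r.aa_type == "K" and abs(r.ca_coord[2]) <= 15.0
                 and r.lipid_accessible]
        assert k_res, "fixture must place Lys inside the membrane"
        expected_native = sum(
            -2.0 * np.exp(-((float(r.ca_coord[2]) + 12.0) ** 2) / (2 * 3.0 ** 2))
            for r in k_res)
        expected_inverted = sum(
            -2.0 * np.exp(-((-float(r.ca_coord[2]) + 12.0) ** 2) / (2 * 3.0 ** 2))
            for r in k_res)
        assert pred.native_score == pytest.approx(expected_native, abs=1e-9)
        assert pred.inverted_score == pytest.approx(expected_inverted,
                                                    abs=1e-9)
        assert pred.native_score < pred.inverted_score

    def test_preflipped_input_prefers_inverted(
            self, hairpin, inside_positive_pset):
        pred = mp.predict_topology(mp.flip_topology(hairpin),
                                   inside_positive_pset)
        assert pred.call == "inverted"

    def test_flip_swaps_scores_exactly(self, hairpin, inside_positive_pset):
        fwd = mp.predict_topology(hairpin, inside_positive_pset)
        rev = mp.predict_topology(mp.flip_topology(hairpin),
                                  inside_positive_pset)
        assert rev.native_score == fwd.inverted_score
        assert rev.inverted_score == fwd.native_score

    def test_symmetric_case_ties_to_native(self, toy_pset, hairpin):
        pred = mp.predict_topology(hairpin, toy_pset)  # all-zero potential
        assert pred.tie_flag and pred.call == "native"


class TestEmbeddingScan:
    def test_grid_dimensions(self, hairpin, inside_positive_pset):
        grid = mp.embedding_scan(hairpin, inside_positive_pset)
        assert grid.scores.shape == (41, 36)
        assert len(grid.z_offsets) == 41 and len(grid.tilt_angles) == 36
        assert grid.z_offsets[0] == -100.0 and grid.z_offsets[-1] == 100.0
        assert grid.tilt_angles[-1] == 350.0

    def test_native_cell_matches_score_structure(
            self, hairpin, inside_positive_pset):
        grid = mp.embedding_scan(hairpin, inside_positive_pset)
        bd = mp.score_structure(hairpin, inside_positive_pset)
        iz0 = int(np.argmin(np.abs(grid.z_offsets)))
        assert grid.scores[iz0, 0] == bd.total
        assert grid.native_score == bd.total

    def test_grid_matches_model_level_transform(
            self, hairpin, inside_positive_pset):
        """The vectorized scan agrees with explicitly transforming the
        model and rescoring (independent route)."""
        grid = mp.embedding_scan(hairpin, inside_positive_pset)
        rng = np.random.default_rng(4)
        for _ in range(5):
            iz = int(rng.integers(0, 41))
            it = int(rng.integers(0, 36))
            moved = mp.transform_embedding(hairpin,
                                           float(grid.z_offsets[iz]),
                                           float(grid.tilt_angles[it]))
            bd = mp.score_structure(moved, inside_positive_pset)
            assert grid.scores[iz, it] == pytest.approx(bd.total, abs=1e-9)

    def test_deterministic(self, hairpin, inside_positive_pset):
        g1 = mp.embedding_scan(hairpin, inside_positive_pset)
        g2 = mp.embedding_scan(hairpin, inside_positive_pset)
        np.testing.assert_array_equal(g1.scores, g2.scores)
        assert g1.argmin == g2.argmin

    def test_symmetric_potential_mirror_symmetry(self):
        """For profiles even in z, scores at (z, θ) and (-z, θ+180°) agree
        for any structure whose rotation center lies on the membrane
        plane."""
        even_well = FitModel("single_gaussian", [0.0, -1.5, 0.0, 5.0],
                             residual=0.0, z_range=(-45.0, 45.0))
        pset = make_toy_pset({("L", "accessible"): even_well,
                              ("W", "inaccessible"): even_well})
        rng = np.random.default_rng(9)
        dists = {("L", True): [fx.Gaussian(25, 0.0, 8.0)],
                 ("W", False): [fx.Gaussian(25, 2.0, 9.0)]}
        (model,) = fx.sample_structure_ensemble(
            fx.FixtureSpec(depth_distributions=dists, seed=13))
        # recenter the COM onto the membrane plane
        shift = model.atoms.coord.mean(axis=0)
        model.atoms.coord = np.asarray(model.atoms.coord) - shift
        for rec in model.residues:
            rec.ca_coord = rec.ca_coord - shift
        grid = mp.embedding_scan(model, pset)
        z = grid.z_offsets
        t = grid.tilt_angles
        for iz in range(len(z)):
            for it in range(len(t)):
                iz2 = len(z) - 1 - iz              # -z
                it2 = int((t[it] + 180.0) % 360.0 // 10)
                # float32 coordinate storage limits the recentering
                assert grid.scores[iz, it] == pytest.approx(
                    grid.scores[iz2, it2], abs=2e-6)


class TestDDG:
    def test_self_mutation_is_zero(self, hairpin, inside_positive_pset):
        site = next(r.residue_index for r in hairpin.residues
                    if r.aa_type == "K")
        pred = mp.predict_ddg(hairpin, site, "K", inside_positive_pset)
        assert pred.ddg == 0.0

    def test_antisymmetry(self):
        leu = FitModel("poly4", [0, 0, 0, 0, -1.0], residual=0.0,
                       z_range=(-45, 45))
        arg = FitModel("poly4", [0, 0, 0, 0, 3.0], residual=0.0,
                       z_range=(-45, 45))
        pset = make_toy_pset({("L", "accessible"): leu,
                              ("R", "accessible"): arg})
        with_leu = fx.sample_structure_ensemble(fx.FixtureSpec(
            depth_distributions={("L", True): [fx.Gaussian(1, 0.0, 1e-9)]},
            seed=6))[0]
        with_arg = fx.sample_structure_ensemble(fx.FixtureSpec(
            depth_distributions={("R", True): [fx.Gaussian(1, 0.0, 1e-9)]},
            seed=6))[0]
        fwd = mp.predict_ddg(with_leu, 1, "R", pset)
        rev = mp.predict_ddg(with_arg, 1, "L", pset)
        assert fwd.ddg == pytest.approx(-rev.ddg, abs=1e-12)

    def test_toy_values(self):
        leu = FitModel("poly4", [0, 0, 0, 0, -1.0], residual=0.0,
                       z_range=(-45, 45))
        arg = FitModel("poly4", [0, 0, 0, 0, 3.0], residual=0.0,
                       z_range=(-45, 45))
        pset = make_toy_pset({("L", "accessible"): leu,
                              ("R", "accessible"): arg})
        dists = {("L", True): [fx.Gaussian(1, 0.0, 1e-9)]}
        (model,) = fx.sample_structure_ensemble(
            fx.FixtureSpec(depth_distributions=dists, seed=6))
        pred = mp.predict_ddg(model, 1, "R", pset)
        assert pred.ddg == pytest.approx(4.0, abs=1e-9)
        assert pred.wt_aa == "L" and pred.accessibility == "accessible"

    def test_outside_membrane_warns_and_clamps(self, caplog):
        leu = FitModel("poly4", [0, 0, 0, 0, -1.0], residual=0.0,
                       z_range=(-45, 45))
        pset = make_toy_pset({("L", "accessible"): leu})
        dists = {("L", True): [fx.Gaussian(1, 70.0, 1e-9)]}
        (model,) = fx.sample_structure_ensemble(
            fx.FixtureSpec(depth_distributions=dists, seed=8))
        with caplog.at_level("WARNING"):
            pred = mp.predict_ddg(model, 1, "A", pset)
        assert "outside the membrane" in caplog.text
        assert pred.ddg == pytest.approx(1.0)
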