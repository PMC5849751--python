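"""Histograms, inverse Boltzmann inversion, fitting, parameter tables."""

import numpy as np
import pytest

import membpot as mp
from membpot import fixtures as fx
from membpot._aa import AA_INDEX, AA_ORDER
from membpot.potentials import (
    CountHistogram,
    FitModel,
    double_gaussian,
    fit_counts,
    fit_energy_profile,
    single_gaussian,
)

KT = 0.593


def empty_hist(n_bins=30, lo=-45.0, width=3.0):
    edges = lo + width * np.arange(n_bins + 1)
    return CountHistogram(bin_edges=edges,
                          counts=np.zeros((20, 2, n_bins)),
                          overflow=np.zeros((20, 2)), n_structures=1)


def ensemble(dists, seed=3):
    return fx.sample_structure_ensemble(
        fx.FixtureSpec(depth_distributions=dists, seed=seed))


class TestAccumulate:
    def test_single_residue_lands_in_its_bin(self):
        dists = {("L", True): [fx.Gaussian(1, 1.4, 1e-9)]}
        hist = mp.accumulate_histograms(ensemble(dists))
        li = AA_INDEX["L"]
        assert hist.counts.sum() == 1
        # z = 1.4 falls in the bin [0, 3)
        bi = int(np.floor((1.4 + 45.0) / 3.0))
        assert hist.counts[li, 0, bi] == 1

    def test_total_equals_eligible_residues(self):
        dists = fx.uniform_background(n_per_cell=50)
        models = ensemble(dists)
        hist = mp.accumulate_histograms(models)
        n_eligible = sum(m.eligible_mask().sum() for m in models)
        assert hist.counts.sum() + hist.overflow.sum() == n_eligible

    def test_doubling_models_doubles_cells(self):
        dists = fx.uniform_background(n_per_cell=40)
        models = ensemble(dists)
        h1 = mp.accumulate_histograms(models)
        h2 = mp.accumulate_histograms(models + models)
        np.testing.assert_array_equal(h2.counts, 2 * h1.counts)

    def test_out_of_range_goes_to_overflow(self):
        dists = {("W", False): [fx.Gaussian(5, 100.0, 0.1)]}
        hist = mp.accumulate_histograms(ensemble(dists))
        assert hist.counts.sum() == 0
        assert hist.overflow[AA_INDEX["W"], 1] == 5

    def test_unflagged_residue_is_error(self, helix):
        with pytest.raises(ValueError, match="classify"):
            mp.accumulate_histograms([helix.copy()])


class TestSmoothing:
    def test_constant_histogram_unchanged(self):
        hist = empty_hist()
        hist.counts[:] = 7.0
        sm = mp.smooth_window3(hist)
        np.testing.assert_allclose(sm.smoothed, 7.0)

    def test_isolated_spike_becomes_mean(self):
        hist = empty_hist()
        hist.counts[0, 0, 10] = 3.0
        sm = mp.smooth_window3(hist)
        np.testing.assert_allclose(sm.smoothed[0, 0, 9:12], 1.0)

    def test_total_preserved_on_random_histograms(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            hist = empty_hist()
            hist.counts[:] = rng.poisson(3.0, hist.counts.shape)
            sm = mp.smooth_window3(hist)
            # independent direct summation per (aa, class) profile
            assert np.allclose(sm.smoothed.sum(axis=-1),
                               hist.counts.sum(axis=-1), atol=1e-9)

    def test_too_few_bins_is_error(self):
        with pytest.raises(ValueError, match="3 bins"):
            mp.smooth_window3(empty_hist(n_bins=2))


class TestInverseBoltzmann:
    def test_uniform_counts_give_log_one_twentieth(self):
        hist = empty_hist()
        hist.counts[:, :, 15] = 5.0
        profiles = mp.counts_to_free_energy(hist, reference_mode="raw")
        for p in profiles:
            assert p.dg[15] == pytest.approx(KT * np.log(1 / 20), abs=1e-12)

    def test_single_occupant_bin_gives_zero(self):
        hist = empty_hist()
        hist.counts[AA_INDEX["G"], 0, 4] = 9.0
        profiles = mp.counts_to_free_energy(hist, reference_mode="raw",
                                            pseudocount=0.0)
        by = {(p.aa, p.accessibility): p for p in profiles}
        assert by[("G", "accessible")].dg[4] == pytest.approx(0.0, abs=1e-12)

    def test_three_to_one_split(self):
        hist = empty_hist()
        hist.counts[AA_INDEX["A"], 0, 20] = 3.0
        hist.counts[AA_INDEX["L"], 0, 20] = 1.0
        profiles = mp.counts_to_free_energy(hist, reference_mode="raw",
                                            pseudocount=0.0)
        by = {(p.aa, p.accessibility): p for p in profiles}
        assert by[("A", "accessible")].dg[20] == pytest.approx(
            KT * np.log(0.75), abs=1e-12)
        assert by[("L", "accessible")].dg[20] == pytest.approx(
            KT * np.log(0.25), abs=1e-12)

    def test_empty_bin_undefined(self):
        hist = empty_hist()
        hist.counts[:, :, 3] = 2.0
        profiles = mp.counts_to_free_energy(hist, reference_mode="raw")
        assert np.isnan(profiles[0].dg[10])
        assert np.isfinite(profiles[0].dg[3])

    def test_energy_sign_convention_negates(self):
        hist = empty_hist()
        hist.counts[:, :, :] = 1.0
        hist.counts[AA_INDEX["K"], 0, 9] = 50.0
        lit = {(p.aa, p.accessibility): p for p in mp.counts_to_free_energy(
            hist, reference_mode="water_referenced")}
        en = {(p.aa, p.accessibility): p for p in mp.counts_to_free_energy(
            hist, reference_mode="water_referenced",
            sign_convention="energy")}
        k_lit = lit[("K", "accessible")].dg
        k_en = en[("K", "accessible")].dg
        np.testing.assert_allclose(k_en, -k_lit)
        assert k_en[9] < 0  # enrichment is favorable under "energy"

    def test_water_referenced_profiles_vanish_in_water(self):
        rng = np.random.default_rng(5)
        hist = empty_hist()
        hist.counts[:] = rng.poisson(50.0, hist.counts.shape)
        profiles = mp.counts_to_free_energy(hist)
        water = np.abs(profiles[0].bin_centers) >= 24.0
        for p in profiles:
            assert np.nanmean(p.dg[water]) == pytest.approx(0.0, abs=1e-10)


class TestFitCounts:
    z = np.arange(-43.5, 45.0, 3.0)

    def test_exact_single_gaussian_recovery(self):
        truth = (5.0, 120.0, -8.0, 6.5)
        fit = fit_counts(self.z, single_gaussian(self.z, *truth),
                         form="single_gaussian")
        np.testing.assert_allclose(fit.params, truth, atol=1e-6)
        assert fit.residual < 1e-10

    def test_constant_data_degenerates_gracefully(self):
        fit = fit_counts(self.z, np.full_like(self.z, 42.0),
                         form="single_gaussian")
        # peak height collapses and the background carries the constant
        assert abs(fit.params[1]) < 1e-3
        assert fit.params[0] == pytest.approx(42.0, abs=1e-3)
        np.testing.assert_allclose(
            single_gaussian(self.z, *fit.params), 42.0, atol=1e-6)

    def test_double_gaussian_recovery_with_noise(self):
        truth = (2.0, 80.0, -15.0, 4.0, 55.0, 12.0, 5.0)
        rng = np.random.default_rng(17)
        y = double_gaussian(self.z, *truth) + rng.normal(0, 0.5, len(self.z))
        fit = fit_counts(self.z, y, form="double_gaussian")
        fitted = double_gaussian(self.z, *fit.params)
        assert np.abs(fitted - double_gaussian(self.z, *truth)).max() < 1.0


class TestFitEnergyProfile:
    z = np.arange(-43.5, 45.0, 3.0)

    def test_quartic_data_selects_poly4(self):
        coeffs = [1e-5, -2e-4, 1e-2, 0.05, -1.2]
        y = np.polyval(coeffs, self.z)
        fit = fit_energy_profile(self.z, y)
        assert fit.form == "poly4"
        np.testing.assert_allclose(fit.params, coeffs, atol=1e-6)

    def test_double_gaussian_data_selects_double_gaussian(self):
        truth = (0.1, -2.5, -14.0, 4.0, 1.5, 10.0, 6.0)
        y = double_gaussian(self.z, *truth)
        fit = fit_energy_profile(self.z, y)
        assert fit.form == "double_gaussian"
        assert np.abs(fit.evaluate(self.z) - y).max() < 1e-6

    def test_tie_prefers_double_gaussian(self):
        from membpot.potentials import select_fit
        dg = FitModel("double_gaussian", [0, 1, 0, 3, 1, 5, 3],
                      residual=0.125, z_range=(-45, 45))
        p4 = FitModel("poly4", [0, 0, 0, 0, 1], residual=0.125,
                      z_range=(-45, 45))
        assert select_fit([p4, dg]).form == "double_gaussian"
        assert select_fit([dg, p4]).form == "double_gaussian"
        # and a strictly better polynomial still wins
        p4b = FitModel("poly4", [0, 0, 0, 0, 1], residual=0.1,
                       z_range=(-45, 45))
        assert select_fit([dg, p4b]).form == "poly4"

    def test_too_few_bins_returns_none(self):
        assert fit_energy_profile(self.z[:5], np.ones(5)) is None


class TestEvaluate:
    def test_poly4_at_zero_is_constant_term(self):
        fit = FitModel("poly4", [3.0, -1.0, 2.0, 0.5, -7.25],
                       residual=0.0, z_range=(-45, 45))
        assert fit.evaluate(0.0) == pytest.approx(-7.25)

    def test_double_gaussian_peak_value(self):
        fit = FitModel("double_gaussian", [1.0, 2.5, -10.0, 3.0, 0.0, 5.0, 2.0],
                       residual=0.0, z_range=(-45, 45))
        assert fit.evaluate(-10.0) == pytest.approx(3.5)

    def test_clamped_beyond_range(self):
        fit = FitModel("poly4", [1e-3, 0, 0, 0, 0], residual=0.0,
                       z_range=(-30.0, 30.0))
        assert fit.evaluate(80.0) == pytest.approx(fit.evaluate(30.0))
        assert fit.evaluate(-95.0) == pytest.approx(fit.evaluate(-30.0))

    def test_unknown_amino_acid_is_error(self, derived_pset):
        with pytest.raises(KeyError):
            derived_pset.evaluate("X", 0.0, True)


class TestPotentialTables:
    def test_round_trip_evaluations(self, derived_pset, tmp_path):
        path = tmp_path / "alpha.tsv"
        mp.write_potential_table(derived_pset, path)
        loaded = mp.read_potential_table(path)
        rng = np.random.default_rng(23)
        z = rng.uniform(-60, 60, 1000)
        for aa in AA_ORDER:
            for acc in (True, False):
                np.testing.assert_allclose(
                    loaded.evaluate(aa, z, acc),
                    derived_pset.evaluate(aa, z, acc), atol=1e-9)
        assert loaded.kT == derived_pset.kT
        assert loaded.reference_mode == derived_pset.reference_mode

    def test_missing_rows_marked_sparse(self, derived_pset, tmp_path, caplog):
        path = tmp_path / "nocys.tsv"
        mp.write_potential_table(derived_pset, path)
        lines = [ln for ln in path.read_text().splitlines()
                 if ln.startswith("#") or ln.split("\t")[1:2] != ["C"]]
        path.write_text("\n".join(lines) + "\n")
        with caplog.at_level("WARNING"):
            loaded = mp.read_potential_table(path)
        assert loaded.profiles[("C", "accessible")].sparse
        assert loaded.evaluate("C", 0.0, True) == 0.0
        assert "C/accessible" in caplog.text

    def test_malformed_numeric_names_row(self, derived_pset, tmp_path):
        path = tmp_path / "bad.tsv"
        mp.write_potential_table(derived_pset, path)
        lines = path.read_text().splitlines()
        # corrupt the first data row's 'a' parameter (column 5)
        fields = lines[5].split("\t")
        fields[4] = "not_a_number"
        lines[5] = "\t".join(fields)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="row"):
            mp.read_potential_table(path)


class TestDerivedSetProperties:
    def test_fit_reproduces_binned_dg_at_stored_residual(self, derived_pset):
        prof = derived_pset.profile("K", True)
        defined = np.isfinite(prof.dg)
        resid = float(np.sum(
            (prof.fit.evaluate(prof.bin_centers[defined])
             - prof.dg[defined]) ** 2))
        assert resid == pytest.approx(prof.fit.residual, rel=1e-6)

    def test_complete_over_amino_acids_and_classes(self, derived_pset):
        assert set(derived_pset.profiles) == {
            (aa, cls) for aa in AA_ORDER
            for cls in ("accessible", "inaccessible")}

    def test_more_data_does_not_move_the_peak(self):
        """Adding structures from the same distributions shifts the
        recovered extremum by less than one bin."""
        dists = fx.uniform_background(n_per_cell=800)
        dists[("K", True)] = [fx.Gaussian(8000, -17.0, 4.0)]
        spec_small = fx.FixtureSpec(depth_distributions=dists, seed=31)
        spec_more = fx.FixtureSpec(depth_distributions=dists, seed=32)
        small = fx.sample_structure_ensemble(spec_small)
        more = small + fx.sample_structure_ensemble(spec_more)
        def k_min(models):
            pset = mp.derive_potential(models)
            prof = pset.profile("K", True)
            z = np.linspace(-30, 30, 1201)
            return z[np.argmin(prof.evaluate(z))]
        assert abs(k_min(small) - k_min(more)) <= 3.0
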