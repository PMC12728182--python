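"""Noise estimation, dip picking, residue and global CEST fits, model
comparison, bootstrap and search diagnostics — on small synthetic data."""

import numpy as np
import pytest

from foldbind import synthetic as syn
from foldbind.analysis import (
    CestDataset,
    FitSpec,
    _CestModel,
    assign_minor_states,
    bootstrap_global,
    compare_models,
    estimate_noise,
    fit_global,
    fit_residue_3site,
    GlobalFitResult,
    grid_search,
    pick_dips,
    robust_noise,
    scheme_from_globals,
    search_crib_boundary,
)
from foldbind.exceptions import InvalidInputError
from foldbind.exchange import ExchangeScheme, MixtureComposition
from foldbind.forward import CestExperiment, CestProfile, ResidueSpinSystem, simulate_profile


def flat_profile(n=100, sigma=0.01, seed=0, step=8.0):
    rng = np.random.default_rng(seed)
    offsets = np.arange(n) * step - n * step / 2
    expt = CestExperiment(b1=20.5, tsat=0.4, offsets=offsets)
    return CestProfile(residue_id=1, experiment=expt, offsets=offsets,
                       intensities=0.8 + rng.normal(0, sigma, n))


class TestEstimateNoise:
    def test_calibrated_on_gaussian_noise(self):
        # Monte Carlo calibration of the second-difference estimator
        est = [estimate_noise(flat_profile(sigma=0.01, seed=s))
               for s in range(20)]
        assert 0.008 <= np.mean(est) <= 0.012

    def test_annihilates_linear_trend(self):
        offsets = np.arange(50) * 8.0
        expt = CestExperiment(b1=20.5, tsat=0.4, offsets=offsets)
        prof = CestProfile(residue_id=1, experiment=expt, offsets=offsets,
                           intensities=0.2 + 0.003 * offsets)
        assert estimate_noise(prof) == pytest.approx(0.0, abs=1e-12)

    def test_dip_curvature_bounded_and_noise_dominates(self):
        offsets = np.arange(-400.0, 400.0, 8.0)
        depth, width = 0.5, 60.0
        clean = 1.0 - depth / (1.0 + (offsets / width) ** 2)
        expt = CestExperiment(b1=20.5, tsat=0.4, offsets=offsets)
        smooth = CestProfile(residue_id=1, experiment=expt, offsets=offsets,
                             intensities=clean)
        rng = np.random.default_rng(0)
        noisy = CestProfile(residue_id=1, experiment=expt, offsets=offsets,
                            intensities=clean + rng.normal(0, 0.01, clean.size))
        s_smooth, s_noisy = estimate_noise(smooth), estimate_noise(noisy)
        assert s_smooth <= 0.1 * depth / np.sqrt(6.0)
        assert s_smooth < 0.25 * s_noisy

    def test_too_few_points(self):
        prof = flat_profile(n=4)
        with pytest.raises(InvalidInputError):
            estimate_noise(prof)

    def test_robust_variant_resists_dips(self):
        # sharp dip (width comparable to the grid step): the mean-square
        # filter inherits the curvature, the median-based variant does not
        offsets = np.arange(-400.0, 400.0, 8.0)
        clean = 1.0 - 0.6 / (1.0 + (offsets / 12.0) ** 2)
        rng = np.random.default_rng(1)
        expt = CestExperiment(b1=20.5, tsat=0.4, offsets=offsets)
        prof = CestProfile(residue_id=1, experiment=expt, offsets=offsets,
                           intensities=clean + rng.normal(0, 0.004, clean.size))
        assert robust_noise(prof) < 0.5 * estimate_noise(prof)
        assert 0.002 < robust_noise(prof) < 0.008


class TestPickDips:
    def _three_dip_profile(self):
        scheme = ExchangeScheme(kon=1e5, koff=30.0, k_ab=60, k_ba=60,
                                k_bc=60, k_cb=60)
        spin = ResidueSpinSystem(residue_id=1, shift_f=118.5, dw_fa=-3.0,
                                 dw_fb=2.0, dw_fc=4.5, r1=1.5, r2_f=5,
                                 r2_b=20, r2_c=20, r2_a=20)
        comp = MixtureComposition(p0=500, r0=150, kd=10)
        expt = CestExperiment(b1=15.0, tsat=0.4,
                              offsets=np.arange(-700.0, 700.0, 8.0))
        prof = simulate_profile(spin, scheme, comp, expt)
        rng = np.random.default_rng(2)
        prof.intensities = prof.intensities + rng.normal(0, 0.002,
                                                         prof.offsets.size)
        return prof, spin

    def test_finds_three_separated_dips(self):
        prof, spin = self._three_dip_profile()
        picks = pick_dips(prof, depth_threshold=10.0,
                          major_shift=spin.shift_f)
        dws = sorted(p - spin.shift_f for p in picks)
        assert len(dws) == 3
        for got, true in zip(dws, (-3.0, 2.0, 4.5)):
            assert abs(got - true) <= 8.0 / 96.3  # one grid step

    def test_flat_noise_gives_nothing(self):
        prof = flat_profile(sigma=0.01, seed=3)
        assert pick_dips(prof, depth_threshold=5.0) == []

    def test_dip_difference_extracts_dw(self):
        # slow-exchange shift difference read directly off the dip spacing
        scheme = ExchangeScheme(kon=1e5, koff=20.0, k_bc=1e-3, k_cb=1e3)
        spin = ResidueSpinSystem(residue_id=1, shift_f=118.5, dw_fb=3.0,
                                 dw_fc=3.0, r1=1.5, r2_f=5, r2_b=25,
                                 r2_c=25)
        comp = MixtureComposition(p0=500, r0=150, kd=10)
        expt = CestExperiment(b1=15.0, tsat=0.4,
                              offsets=np.arange(-500.0, 500.0, 8.0))
        prof = simulate_profile(spin, scheme, comp, expt)
        picks = pick_dips(prof, depth_threshold=20.0,
                          major_shift=spin.shift_f, sigma=0.002)
        major = prof.experiment.hz_to_ppm(
            prof.offsets[np.argmin(prof.intensities)]
        )
        assert len(picks) >= 1
        assert abs((picks[0] - major) - 3.0) <= 2 * 8.0 / 96.3


def small_dataset(seed=3, sigma=0.0, scheme=None):
    scen = syn.make_reduced_scenario(seed=seed, sigma=sigma,
                                     scheme=scheme or syn.STUDY_SCHEME)
    ds, truth = syn.generate_cest_dataset(scen)
    if sigma == 0.0:
        for p in ds.profiles:
            p.sigmas = np.full(p.offsets.size, 0.004)
    ds.apply_exclusion_masks()
    return scen, ds, truth


def truth_residue_init(truth):
    keys = ("dw_fa", "dw_fb", "dw_fc", "r1", "r2_f", "r2_b", "r2_c")
    return {rid: {k: v for k, v in tr.items() if k in keys}
            for rid, tr in truth["residues"].items()}


class TestResidueFit:
    def test_noiseless_single_residue_recovery(self):
        # truth must satisfy the fit's R2B = R2C tie for exact recovery
        from dataclasses import replace as dc_replace

        scheme3 = ExchangeScheme(kon=7.3e5, koff=56.0, k_bc=89.0, k_cb=94.0)
        scen = syn.make_reduced_scenario(seed=5, sigma=0.0, scheme=scheme3)
        scen.spins = {rid: dc_replace(s, r2_c=s.r2_b)
                      for rid, s in scen.spins.items()}
        ds, truth = syn.generate_cest_dataset(scen)
        for p in ds.profiles:
            p.sigmas = np.full(p.offsets.size, 0.004)
        ds.apply_exclusion_masks()
        rid = 359  # well-separated B and C dips
        tr = truth["residues"][rid]
        fit = fit_residue_3site(
            ds, rid,
            residue_init={"dw_fb": tr["dw_fb"] + 0.3,
                          "dw_fc": tr["dw_fc"] - 0.3},
        )
        assert fit.global_params["koff"] == pytest.approx(56.0, rel=0.01)
        assert fit.global_params["k_bc"] == pytest.approx(89.0, rel=0.01)
        assert fit.global_params["k_cb"] == pytest.approx(94.0, rel=0.01)
        rp = fit.residue_params[rid]
        assert rp["dw_fb"] == pytest.approx(tr["dw_fb"], abs=0.01)
        assert rp["dw_fc"] == pytest.approx(tr["dw_fc"], abs=0.01)

    def test_population_constraint_enforced(self):
        scen, ds, truth = small_dataset(seed=5)
        model = _CestModel(ds.subset([339]), FitSpec(model="3site"))
        from foldbind.exchange import bound_fraction, partition_populations
        for x in (model.x0(), model.x0() + 0.05):
            g, _ = model.unpack(x)
            scheme = scheme_from_globals("3site", g)
            pops = partition_populations(model.total_bound, scheme)
            assert pops.p_b + pops.p_c == pytest.approx(
                bound_fraction(ds.composition), abs=1e-14)

    def test_zero_exchange_chi2_consistent_with_noise(self):
        # no-exchange data: the constrained fit flattens its dips and the
        # chi-square matches the noise dof
        scen = syn.make_reduced_scenario(seed=9, sigma=0.004)
        scen.spins = {rid: s.__class__(**{**s.__dict__, "dw_fa": 0.0,
                                          "dw_fb": 0.0, "dw_fc": 0.0})
                      for rid, s in scen.spins.items()}
        ds, truth = syn.generate_cest_dataset(scen)
        ds.apply_exclusion_masks()
        fit = fit_residue_3site(ds, 339, residue_init={"dw_fb": 0.0,
                                                       "dw_fc": 0.0})
        dof = fit.dof
        assert abs(fit.chi2 - dof) <= 3 * np.sqrt(2 * dof)


class TestAssignment:
    def test_swap_test_keeps_true_assignment(self):
        scen, ds, truth = small_dataset(seed=21, sigma=0.002)
        rid = 359  # partially shifted intermediate: well-separated B and C
        tr = truth["residues"][rid]
        fit = fit_residue_3site(ds, rid,
                                residue_init={"dw_fb": tr["dw_fb"],
                                              "dw_fc": tr["dw_fc"]})
        res = assign_minor_states(ds, rid, fit)
        assert res.accepted == "original"
        if res.swapped is not None and not res.reverted:
            assert res.swapped.chi2 > fit.chi2

    def test_degenerate_dips_flagged(self):
        scen, ds, truth = small_dataset(seed=5)
        fit = fit_residue_3site(ds, 339, residue_init={"dw_fb": 2.0,
                                                       "dw_fc": 2.0})
        fit.residue_params[339]["dw_fc"] = fit.residue_params[339]["dw_fb"]
        res = assign_minor_states(ds, 339, fit)
        assert res.accepted == "ambiguous"

    def test_intermediate_less_populated_than_complex(self):
        # with the study rates the B state is less populated than C
        from foldbind.exchange import bound_fraction, partition_populations
        pops = partition_populations(
            bound_fraction(syn.STUDY_COMPOSITION), syn.STUDY_SCHEME)
        assert pops.p_b > 0  # sanity
        scheme3 = ExchangeScheme(kon=7.3e5, koff=56.0, k_bc=89.0, k_cb=94.0)
        pops3 = partition_populations(
            bound_fraction(syn.STUDY_COMPOSITION), scheme3)
        assert pops3.p_b < pops3.p_c * 1.2  # k_bc < k_cb keeps B below C


class TestGlobalFit:
    def test_noiseless_truth_is_fixed_point(self):
        scen, ds, truth = small_dataset(seed=3, sigma=0.0)
        spec = FitSpec(
            model="4site", crib_set=scen.crib_truth,
            global_init={"koff": 56.0, "kex_ab": 136.0, "kex_bc": 183.0,
                         "keq_ab": 72 / 64, "keq_bc": 89 / 94},
            residue_init=truth_residue_init(truth),
        )
        model = _CestModel(ds, spec)
        assert model.chi2(model.x0()) < 1e-6

    def test_masked_points_do_not_contribute(self):
        scen, ds, truth = small_dataset(seed=3)
        spec = FitSpec(model="4site", crib_set=scen.crib_truth,
                       residue_init=truth_residue_init(truth),
                       global_init={"koff": 56.0, "kex_ab": 136.0,
                                    "kex_bc": 183.0, "keq_ab": 72 / 64,
                                    "keq_bc": 89 / 94})
        model = _CestModel(ds, spec)
        chi2_before = model.chi2(model.x0())
        masked_idx = np.nonzero(~ds.profiles[0].mask)[0]
        assert masked_idx.size > 0
        ds.profiles[0].intensities[masked_idx[0]] += 100.0
        model2 = _CestModel(ds, spec)
        assert model2.chi2(model2.x0()) == pytest.approx(chi2_before,
                                                         rel=1e-12)

    def test_r2b_r2c_tie_honoured(self):
        scen, ds, truth = small_dataset(seed=3)
        spec = FitSpec(model="4site", crib_set=scen.crib_truth,
                       r2b_eq_r2c=frozenset([339]))
        model = _CestModel(ds, spec)
        names_339 = [p.name for p in model.params if p.rid == 339]
        assert "r2_c" not in names_339
        _, per_res = model.unpack(model.x0())
        assert per_res[339]["r2_c"] == per_res[339]["r2_b"]


class TestCompareModels:
    def _mk(self, model, chi2, n_points, n_free):
        return GlobalFitResult(model=model, global_params={},
                               residue_params={}, chi2=chi2,
                               n_points=n_points, n_free=n_free)

    def test_identical_chi2_prefers_simpler(self):
        res3 = self._mk("3site", 100.0, 500, 20)
        res4 = self._mk("4site", 100.0, 500, 25)
        cmp_ = compare_models(res3, res4)
        assert cmp_.f_stat == 0.0
        assert cmp_.p_value == 1.0
        assert cmp_.preferred == "3site"

    def test_large_improvement_prefers_complex(self):
        res3 = self._mk("3site", 1000.0, 500, 20)
        res4 = self._mk("4site", 450.0, 500, 25)
        cmp_ = compare_models(res3, res4)
        assert cmp_.preferred == "4site"
        assert cmp_.p_value < 1e-6

    def test_worse_complex_model(self):
        res3 = self._mk("3site", 100.0, 500, 20)
        res4 = self._mk("4site", 120.0, 500, 25)
        assert compare_models(res3, res4).preferred == "3site"


class TestBootstrap:
    def test_n_zero_empty_summary(self):
        scen, ds, truth = small_dataset(seed=3)
        spec = FitSpec(model="4site", crib_set=scen.crib_truth)
        point = GlobalFitResult(model="4site",
                                global_params=spec.default_global_init(),
                                residue_params={}, chi2=0.0, n_points=1,
                                n_free=0)
        summary = bootstrap_global(ds, spec, point, n=0, seed=0)
        assert summary.n_replicates == 0
        assert summary.ci68 == {}

    def test_resampled_profile_lengths_preserved(self):
        scen, ds, truth = small_dataset(seed=3)
        spec = FitSpec(model="4site", crib_set=scen.crib_truth,
                       residue_init=truth_residue_init(truth),
                       global_init={"koff": 56.0, "kex_ab": 136.0,
                                    "kex_bc": 183.0, "keq_ab": 72 / 64,
                                    "keq_bc": 89 / 94})
        model = _CestModel(ds, spec)
        rng = np.random.default_rng(0)
        for sl in model.row_slices:
            m = sl.stop - sl.start
            counts = np.bincount(rng.integers(0, m, size=m), minlength=m)
            assert counts.sum() == m  # multinomial weights preserve size


class TestSearchAndGrid:
    @pytest.fixture(scope="class")
    def crib_dataset(self):
        # 2 anchored residues among 4, tiny grids for speed
        carrier, larmor = 118.5, 96.3
        expts = [
            CestExperiment(b1=10.3, tsat=0.4,
                           offsets=np.arange(-224.0, 224.0, 28.0),
                           scheme="dante", dante_window=448.0,
                           larmor_15n=larmor, carrier=carrier),
            CestExperiment(b1=68.6, tsat=0.4,
                           offsets=np.arange(-1450.0, 1450.0, 181.0),
                           scheme="cw", larmor_15n=larmor, carrier=carrier),
        ]
        roster = {325: "crib", 327: "crib", 330: "mre1_helix",
                  333: "mre2"}
        scen = syn.make_default_scenario(seed=17, roster=roster,
                                         sigma=0.004, experiments=expts)
        ds, truth = syn.generate_cest_dataset(scen)
        ds.apply_exclusion_masks()
        return scen, ds, truth

    def _spec(self, scen, truth, crib):
        return FitSpec(
            model="4site", crib_set=crib,
            global_init={"koff": 56.0, "kex_ab": 136.0, "kex_bc": 183.0,
                         "keq_ab": 72 / 64, "keq_bc": 89 / 94},
            residue_init=truth_residue_init(truth),
            ftol=1e-6, max_nfev=120,
        )

    def test_boundary_search_recovers_crib_truth(self, crib_dataset):
        scen, ds, truth = crib_dataset
        spec = self._spec(scen, truth, scen.crib_truth)
        warm = fit_global(ds, spec)
        res = search_crib_boundary(ds, spec, (325, 330), warm_start=warm)
        assert res.best_set == frozenset({325, 327})
        assert not res.no_crib

    def test_single_residue_range(self, crib_dataset):
        scen, ds, truth = crib_dataset
        spec = self._spec(scen, truth, scen.crib_truth)
        res = search_crib_boundary(ds, spec, (325, 325))
        assert len(res.trace) <= 1 + 0  # at most one candidate evaluated

    def test_grid_search_minimum_near_global_fit(self, crib_dataset):
        scen, ds, truth = crib_dataset
        spec = self._spec(scen, truth, scen.crib_truth)
        point = fit_global(ds, spec)
        ka = point.global_params["kex_ab"]
        kb = point.global_params["kex_bc"]
        grid = grid_search(ds, spec, np.array([ka / 1.6, ka, ka * 1.6]),
                           np.array([kb / 1.6, kb, kb * 1.6]),
                           warm_start=point)
        # the centre node re-optimises the same optimum; allow float-level
        # disagreement between two approximate minimisations
        assert np.all(grid["chi2"] >= point.chi2 - 1e-4 * point.chi2)
        best = grid.loc[grid["chi2"].idxmin()]
        assert best["kex_ab"] == pytest.approx(ka)
        assert best["kex_bc"] == pytest.approx(kb)


def test_duplicate_profiles_rejected():
    scen, ds, truth = small_dataset(seed=3)
    with pytest.raises(InvalidInputError):
        CestDataset(profiles=ds.profiles + [ds.profiles[0]],
                    composition=ds.composition, residues=ds.residues)
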