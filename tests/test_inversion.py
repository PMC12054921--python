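import numpy as np
import pytest

from mieinvert import (
    DielectricSpectrum,
    ExtinctionSpectrum,
    FitConfig,
    OscillatorBand,
    OscillatorSet,
    SpectralGrid,
    SphereModel,
    eval_permittivity,
    fit_permittivity_direct,
    init_case1,
    init_case2,
    match_bands,
    objective_S,
    reconstruct_from_qext,
    reconstruction_error_metrics,
    residuals_qext,
    simulate_given_qext,
)
from mieinvert.inversion import FitResult


class TestResiduals:
    def test_self_consistency(self, three_band_set, coarse_grid, sphere):
        given, _ = simulate_given_qext(three_band_set, sphere, coarse_grid)
        r = residuals_qext(three_band_set, given, sphere)
        np.testing.assert_allclose(r, 0.0, atol=1e-14)

    def test_zero_strength_model(self, coarse_grid, sphere):
        params = OscillatorSet(
            [OscillatorBand(1000.0, 0.0, 10.0)], eps_inf=1.0
        )  # eps == medium^2 -> no scatterer
        given = ExtinctionSpectrum(
            coarse_grid, np.linspace(0.5, 2.0, len(coarse_grid))
        )
        r = residuals_qext(params, given, sphere)
        np.testing.assert_allclose(r, -given.qext, atol=1e-14)

    def test_one_band_toy(self, coarse_grid, sphere):
        # oracle: two explicit forward evaluations
        truth = OscillatorSet([OscillatorBand(1500.0, 150.0, 30.0)], eps_inf=2.25)
        trial = OscillatorSet([OscillatorBand(1500.0, 150.0, 40.0)], eps_inf=2.25)
        given, _ = simulate_given_qext(truth, sphere, coarse_grid)
        model, _ = simulate_given_qext(trial, sphere, coarse_grid)
        r = residuals_qext(trial, given, sphere)
        np.testing.assert_allclose(r, model.qext - given.qext, atol=1e-14)
        s = objective_S(trial, given, sphere)
        assert s == pytest.approx(float(np.dot(r, r)), rel=1e-12)
        assert s > 0

    def test_objective_arithmetic(self):
        r = np.array([0.1, -0.2, 0.3])
        assert float(np.dot(r, r)) == pytest.approx(0.14, rel=1e-12)


class TestInitializers:
    def test_case1_spacing(self):
        cfg = FitConfig(n_bands=25, init_scheme="case1")
        init = init_case1(cfg)
        nu0 = np.array([b.nu0 for b in init.bands])
        assert nu0[0] == 500.0 and nu0[-1] == 4000.0
        np.testing.assert_allclose(np.diff(nu0), 3500.0 / 24, rtol=1e-12)
        assert all(b.nup == 20.0 and b.gamma == 20.0 for b in init.bands)

    def test_case1_two_bands(self):
        init = init_case1(FitConfig(n_bands=2, init_scheme="case1"))
        assert [b.nu0 for b in init.bands] == [500.0, 4000.0]

    def test_case1_minimum(self):
        with pytest.raises(ValueError):
            init_case1(FitConfig(n_bands=1, init_scheme="case1"))

    def test_case2_default_allocation(self):
        cfg = FitConfig(n_bands=25, init_scheme="case2")
        init = init_case2(cfg)
        nu0 = np.array([b.nu0 for b in init.bands])
        in_a = nu0[(nu0 >= 500.0) & (nu0 <= 2200.0)]
        in_c = nu0[(nu0 >= 2800.0) & (nu0 <= 3500.0)]
        assert in_a.size == 20 and in_c.size == 5
        np.testing.assert_allclose(np.diff(in_a), 1700.0 / 19, rtol=1e-12)
        np.testing.assert_allclose(np.diff(in_c), 700.0 / 4, rtol=1e-12)
        # silent windows are empty
        assert not np.any((nu0 > 2200.0) & (nu0 < 2800.0))
        assert not np.any(nu0 > 3500.0)

    def test_case2_count_mismatch(self):
        cfg = FitConfig(
            n_bands=10,
            init_scheme="case2",
            intervals=((500.0, 2200.0, 5), (2800.0, 3500.0, 2)),
        )
        with pytest.raises(ValueError):
            init_case2(cfg)

    def test_case2_degenerate_equals_case1(self):
        cfg = FitConfig(
            n_bands=8,
            init_scheme="case2",
            intervals=((500.0, 4000.0, 8),),
        )
        a = init_case2(cfg)
        b = init_case1(FitConfig(n_bands=8, init_scheme="case1"))
        assert a.to_dict() == b.to_dict()


class TestReconstructFromQext:
    def test_parameter_recovery(self, three_band_set, sphere):
        grid = SpectralGrid.uniform(500.0, 4000.0, 400)
        given, _ = simulate_given_qext(three_band_set, sphere, grid)
        cfg = FitConfig(n_bands=6, init_scheme="case1")
        res = reconstruct_from_qext(given, sphere, cfg)
        m = match_bands(res.params, three_band_set, strength_floor=1e-4)
        assert m.n_unmatched_truth == 0
        assert np.max(np.abs(m.delta_nu0)) < 1.0
        truth_eps = eval_permittivity(three_band_set, grid)
        _, rel_imag = reconstruction_error_metrics(res, truth_eps)
        assert rel_imag < 0.05
        # surplus bands carry negligible strength
        matched = {id(b) for b, _ in m.pairs}
        surplus = [
            b for b in res.params.bands
            if id(b) not in matched
        ]
        strongest = max(b.nup**2 for b in res.params.bands)
        assert all(b.nup**2 < 1e-3 * strongest for b in surplus)

    def test_zero_spectrum(self, sphere):
        # the exact zero model (nup = 0, eps_inf = medium^2) is feasible;
        # start eps_inf moderately above 1 — from a high-contrast start the
        # optimizer can stall on the Qext ~ 2 extinction-paradox plateau
        grid = SpectralGrid.uniform(500.0, 4000.0, 60)
        given = ExtinctionSpectrum(grid, np.zeros(60))
        cfg = FitConfig(
            n_bands=2, init_scheme="case1", eps_inf_init=1.5, max_nfev=400
        )
        res = reconstruct_from_qext(given, sphere, cfg)
        assert res.objective_S < 1e-6
        # residual bands are negligible: peak eps'' contribution ~ 0
        for b in res.params.bands:
            assert b.nup**2 / (b.nu0 * b.gamma) < 1e-3
        assert res.params.eps_inf == pytest.approx(1.0, abs=1e-3)

    def test_determinism(self, one_band_set, sphere):
        grid = SpectralGrid.uniform(500.0, 4000.0, 100)
        given, _ = simulate_given_qext(one_band_set, sphere, grid)
        cfg = FitConfig(n_bands=2, init_scheme="case1", max_nfev=60)
        r1 = reconstruct_from_qext(given, sphere, cfg)
        r2 = reconstruct_from_qext(given, sphere, cfg)
        assert r1.params.to_dict() == r2.params.to_dict()
        assert r1.objective_S == r2.objective_S
        np.testing.assert_array_equal(r1.residuals, r2.residuals)

    def test_monotone_improvement_and_s_consistency(self, one_band_set, sphere):
        grid = SpectralGrid.uniform(500.0, 4000.0, 100)
        given, _ = simulate_given_qext(one_band_set, sphere, grid)
        cfg = FitConfig(n_bands=3, init_scheme="case1", max_nfev=40)
        res = reconstruct_from_qext(given, sphere, cfg)
        assert res.objective_S <= res.initial_S
        assert res.objective_S == pytest.approx(
            float(np.dot(res.residuals, res.residuals)), rel=1e-10
        )

    def test_feasibility_of_returned_params(self, three_band_set, sphere):
        grid = SpectralGrid.uniform(500.0, 4000.0, 150)
        given, _ = simulate_given_qext(three_band_set, sphere, grid)
        cfg = FitConfig(n_bands=5, init_scheme="case1", max_nfev=60)
        res = reconstruct_from_qext(given, sphere, cfg)
        for b in res.params.bands:
            assert b.nup >= 0
            assert b.gamma > 0
            assert 400.0 <= b.nu0 <= 4100.0
        assert 1.0 <= res.params.eps_inf <= 6.0

    def test_non_finite_input_rejected(self, sphere):
        grid = SpectralGrid.uniform(500.0, 4000.0, 10)
        q = np.zeros(10)
        given = ExtinctionSpectrum(grid, q)
        given.qext = given.qext.copy()
        given.qext[3] = np.nan  # bypass constructor validation deliberately
        cfg = FitConfig(n_bands=2, init_scheme="case1")
        with pytest.raises(ValueError):
            reconstruct_from_qext(given, sphere, cfg)

    def test_noise_robustness(self, sphere):
        from mieinvert import NoiseModel

        grid = SpectralGrid.uniform(500.0, 4000.0, 300)
        truth = OscillatorSet(
            [
                OscillatorBand(1100.0, 250.0, 35.0),
                OscillatorBand(1730.0, 200.0, 25.0),
                OscillatorBand(2900.0, 150.0, 30.0),
            ],
            eps_inf=2.3,
        )
        medians = []
        for seed in range(10):
            obs, _ = simulate_given_qext(
                truth, sphere, grid, NoiseModel(relative_sigma=0.01, seed=seed)
            )
            cfg = FitConfig(n_bands=6, init_scheme="case1", max_nfev=80)
            res = reconstruct_from_qext(obs, sphere, cfg)
            m = match_bands(res.params, truth, strength_floor=1e-4)
            assert m.n_unmatched_truth == 0
            medians.append(np.median(np.abs(m.delta_nu0)))
        assert np.median(medians) < 5.0


class TestFitPermittivityDirect:
    def test_self_recovery(self, three_band_set):
        # same-M self-recovery from a perturbed explicit start (equal band
        # count leaves no surplus oscillators to bridge large center gaps)
        grid = SpectralGrid.uniform(500.0, 4000.0, 400)
        eps = eval_permittivity(three_band_set, grid)
        start = OscillatorSet(
            [
                OscillatorBand(b.nu0 + 40.0, 0.7 * b.nup, b.gamma + 10.0)
                for b in three_band_set.bands
            ],
            eps_inf=2.0,
        )
        cfg = FitConfig(n_bands=3, init_scheme="explicit", explicit_init=start)
        res, errs = fit_permittivity_direct(eps, cfg)
        maxeps = np.max(np.abs(eps.eps_imag))
        assert np.max(np.abs(errs.e_imag)) < 1e-6 * maxeps
        m = match_bands(res.params, three_band_set)
        assert np.max(np.abs(m.delta_nu0)) < 0.1

    def test_constant_spectrum(self):
        grid = SpectralGrid.uniform(500.0, 4000.0, 80)
        eps = DielectricSpectrum(grid, np.full(80, 2.4), np.zeros(80))
        cfg = FitConfig(n_bands=2, init_scheme="case1", max_nfev=300)
        res, errs = fit_permittivity_direct(eps, cfg)
        assert res.params.eps_inf == pytest.approx(2.4, abs=1e-3)
        assert all(b.nup < 0.5 for b in res.params.bands)

    def test_direct_and_inverse_agree(self, three_band_set, sphere):
        grid = SpectralGrid.uniform(500.0, 4000.0, 300)
        eps = eval_permittivity(three_band_set, grid)
        given, _ = simulate_given_qext(three_band_set, sphere, grid)
        cfg = FitConfig(n_bands=6, init_scheme="case1")
        res_d, _ = fit_permittivity_direct(eps, cfg)
        res_q = reconstruct_from_qext(given, sphere, cfg)
        md = match_bands(res_d.params, three_band_set, strength_floor=1e-4)
        mq = match_bands(res_q.params, three_band_set, strength_floor=1e-4)
        assert md.n_unmatched_truth == 0 and mq.n_unmatched_truth == 0
        # both routes land on the same band centers
        centers_d = sorted(b.nu0 for b, _ in md.pairs)
        centers_q = sorted(b.nu0 for b, _ in mq.pairs)
        np.testing.assert_allclose(centers_d, centers_q, atol=1.0)

    def test_antisym_basis_runs(self):
        grid = SpectralGrid.uniform(500.0, 4000.0, 150)
        truth = OscillatorSet([OscillatorBand(1500.0, 150.0, 30.0)], eps_inf=2.25)
        eps = eval_permittivity(truth, grid)
        cfg = FitConfig(n_bands=3, init_scheme="case1", max_nfev=400)
        res, errs = fit_permittivity_direct(eps, cfg, basis="antisym")
        assert res.antisym_params is not None
        assert res.objective_S < res.initial_S

    def test_unknown_basis(self):
        grid = SpectralGrid.uniform(500.0, 4000.0, 10)
        eps = DielectricSpectrum(grid, np.full(10, 2.0), np.zeros(10))
        with pytest.raises(ValueError):
            fit_permittivity_direct(eps, FitConfig(n_bands=2), basis="fourier")


class TestMatchBands:
    def test_identical_sets(self, three_band_set):
        m = match_bands(three_band_set, three_band_set)
        assert len(m.pairs) == 3
        np.testing.assert_array_equal(m.delta_nu0, 0.0)
        np.testing.assert_array_equal(m.delta_nup, 0.0)
        assert m.n_unmatched_fitted == 0 and m.n_unmatched_truth == 0

    def test_dead_band_discarded(self, three_band_set):
        fitted = OscillatorSet(
            list(three_band_set.bands) + [OscillatorBand(2000.0, 1e-8, 10.0)],
            eps_inf=2.3,
        )
        m = match_bands(fitted, three_band_set)
        assert len(m.discarded_fitted) == 1
        assert len(m.pairs) == 3
        np.testing.assert_array_equal(m.delta_nu0, 0.0)

    def test_order_invariance(self, three_band_set):
        permuted = OscillatorSet(list(reversed(three_band_set.bands)), eps_inf=2.3)
        m1 = match_bands(three_band_set, three_band_set)
        m2 = match_bands(permuted, three_band_set)
        np.testing.assert_array_equal(m1.delta_nu0, m2.delta_nu0)


class TestErrorMetrics:
    def _result_for(self, oset, grid):
        eps = eval_permittivity(oset, grid)
        return FitResult(
            params=oset,
            objective_S=0.0,
            residuals=np.zeros(len(grid)),
            model_spectrum=eps,
            converged=True,
            n_evals=0,
            initial_S=0.0,
        )

    def test_exact_fit_zero_error(self, three_band_set, coarse_grid):
        truth = eval_permittivity(three_band_set, coarse_grid)
        res = self._result_for(three_band_set, coarse_grid)
        assert reconstruction_error_metrics(res, truth) == (0.0, 0.0)

    def test_scaled_imag(self, three_band_set, coarse_grid):
        truth = eval_permittivity(three_band_set, coarse_grid)
        scaled = DielectricSpectrum(
            coarse_grid, truth.eps_real, truth.eps_imag * 1.1
        )
        res = self._result_for(three_band_set, coarse_grid)
        # fitted = truth, target scaled by 1.1 -> relative error 0.1/1.1
        _, rel_imag = reconstruction_error_metrics(res, scaled)
        assert rel_imag == pytest.approx(0.1 / 1.1, rel=1e-9)
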