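import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid, solve_ivp

from pibflow.io_core import ParametricMap
from pibflow.kinetic_cbf import (
    KineticConfig,
    WeightedIntegralFitter,
    cbf_image,
    fit_nlls,
    fit_weighted_integral,
    k1_to_cbf,
    model_tac,
)


@pytest.fixture(scope="module")
def cp(gamma_input):
    """Undispersed plasma input (what a corrected IDIF provides)."""
    return gamma_input[0]


@pytest.fixture(scope="module")
def fitter(cp, schedule):
    return WeightedIntegralFitter(cp, schedule, KineticConfig())


class TestModelTac:
    def test_zero_k1_gives_zero(self, cp, schedule):
        assert np.allclose(model_tac(0.0, 0.1, cp, schedule), 0.0)

    def test_zero_k2_is_cumulative_integral(self, cp, schedule):
        """With k2 = 0 the tissue curve is K1 times the running integral of
        the plasma input."""
        k1 = 0.3
        got = model_tac(k1, 0.0, cp, schedule)
        t = np.arange(0.0, 180.0 + 0.125, 0.25)
        cp_d = cp.sample_plasma(t)
        integral = np.concatenate([[0.0], cumulative_trapezoid(cp_d, t)]) * k1 / 60.0
        cum2 = np.concatenate([[0.0], cumulative_trapezoid(integral, t)])
        frames = np.arange(21)
        starts, ends = schedule.starts[frames], schedule.ends[frames]
        means = (np.interp(ends, t, cum2) - np.interp(starts, t, cum2)) / (ends - starts)
        assert np.allclose(got, means, rtol=1e-6)

    def test_matches_stiff_ode_solver(self, cp, schedule):
        """Arbitrary (k1, k2) frame means agree with an independent ODE
        solve on a fine grid within 0.1%."""
        k1, k2 = 0.42, 0.23
        got = model_tac(k1, k2, cp, schedule)

        def rhs(t, y):
            return (k1 / 60.0) * cp.sample_plasma(np.array([t]))[0] - (k2 / 60.0) * y[0]

        sol = solve_ivp(rhs, (0, 180), [0.0], rtol=1e-10, atol=1e-13,
                        dense_output=True, max_step=1.0)
        fine = np.arange(0.0, 180.0 + 0.05, 0.1)
        c = sol.sol(fine)[0]
        cum = np.concatenate([[0.0], cumulative_trapezoid(c, fine)])
        frames = np.arange(21)
        means = (np.interp(schedule.ends[frames], fine, cum)
                 - np.interp(schedule.starts[frames], fine, cum)) / schedule.durations[frames]
        assert np.max(np.abs(got - means)) / means.max() < 1e-3

    def test_negative_rates_rejected(self, cp, schedule):
        with pytest.raises(ValueError):
            model_tac(-0.1, 0.1, cp, schedule)


class TestWeightedIntegralFit:
    def test_ratio_monotone_in_k2(self, fitter):
        ratio = fitter.basis_integrals[:, 1] / fitter.basis_integrals[:, 0]
        d = np.diff(ratio)
        assert np.all(d < 0) or np.all(d > 0)

    def test_recovers_operating_point(self, cp, schedule):
        """A noise-free TAC at the healthy-control operating point
        (K1 = 0.27 1/min) is recovered within 1%."""
        tac = model_tac(0.27, 0.1, cp, schedule)
        k1, k2 = fit_weighted_integral(tac, cp, schedule)
        assert k1 == pytest.approx(0.27, rel=0.01)
        assert k2 == pytest.approx(0.1, rel=0.05)

    def test_zero_tac_gives_zero_k1(self, fitter):
        res = fitter.fit(np.zeros((1, fitter.frames.size)))
        assert res["k1"][0] == 0.0
        assert not res["flags"][0]

    def test_scale_equivariance(self, cp, schedule, fitter):
        """Scaling both TAC and input by c > 0 leaves (k1, k2) unchanged;
        scaling only the TAC scales k1 linearly."""
        tac = model_tac(0.3, 0.15, cp, schedule)
        r1 = fitter.fit(tac[None, :])
        r2 = fitter.fit(5.0 * tac[None, :])
        assert r2["k1"][0] == pytest.approx(5.0 * r1["k1"][0], rel=1e-9)
        assert r2["k2"][0] == pytest.approx(r1["k2"][0], rel=1e-9)

    def test_agrees_with_nlls_oracle(self, cp, schedule, fitter, rng):
        """Noise-free weighted-integral estimates match nonlinear least
        squares within 1% (k1) / 5% (k2) across the physiological range."""
        n = 25
        k1s = rng.uniform(0.1, 0.5, n)
        k2s = rng.uniform(0.05, 0.3, n)
        tacs = np.stack([model_tac(a, b, cp, schedule) for a, b in zip(k1s, k2s)])
        wi = fitter.fit(tacs)
        for i in range(n):
            k1_n, k2_n = fit_nlls(tacs[i], cp, schedule)
            assert wi["k1"][i] == pytest.approx(k1_n, rel=0.01)
            assert wi["k2"][i] == pytest.approx(k2_n, rel=0.05)

    def test_noise_free_bias_under_one_percent(self, cp, schedule, fitter):
        """Parameter recovery bias < 1% for k1 over the stated grid."""
        k1s = np.linspace(0.1, 0.5, 5)
        k2s = np.linspace(0.05, 0.3, 4)
        for k1 in k1s:
            for k2 in k2s:
                tac = model_tac(k1, k2, cp, schedule)
                res = fitter.fit(tac[None, :])
                assert res["k1"][0] == pytest.approx(k1, rel=0.01)


class TestNlls:
    def test_self_consistency(self, cp, schedule):
        tac = model_tac(0.35, 0.12, cp, schedule)
        k1, k2 = fit_nlls(tac, cp, schedule)
        assert k1 == pytest.approx(0.35, rel=1e-4)
        assert k2 == pytest.approx(0.12, rel=1e-3)

    def test_residual_rises_away_from_truth(self, cp, schedule):
        tac = model_tac(0.3, 0.1, cp, schedule)

        def rss(k1):
            return np.sum((model_tac(k1, 0.1, cp, schedule) - tac) ** 2)

        assert rss(0.33) > rss(0.3)
        assert rss(0.27) > rss(0.3)

    def test_matches_grid_search_minimum(self, cp, schedule):
        """NLLS lands on the same minimum as a brute-force lattice search."""
        tac = model_tac(0.28, 0.14, cp, schedule)
        k1_grid = np.linspace(0.2, 0.4, 21)
        k2_grid = np.linspace(0.05, 0.25, 21)
        best = min(
            ((a, b, np.sum((model_tac(a, b, cp, schedule) - tac) ** 2))
             for a in k1_grid for b in k2_grid),
            key=lambda x: x[2],
        )
        k1, k2 = fit_nlls(tac, cp, schedule)
        assert abs(k1 - best[0]) <= (k1_grid[1] - k1_grid[0])
        assert abs(k2 - best[1]) <= (k2_grid[1] - k2_grid[0])


class TestK1ToCbf:
    def test_healthy_frontal_operating_point(self):
        """K1 = 0.2704 1/min maps back to CBF = 41.6 mL/min/100 g at E=0.65."""
        m = ParametricMap(np.full((2, 2, 2), 0.2704), np.eye(4), "K1")
        cbf = k1_to_cbf(m)
        assert np.allclose(cbf.data, 41.6)
        assert cbf.quantity == "CBF"

    def test_zero_maps_to_zero_and_round_trip(self, rng):
        m = ParametricMap(rng.random((3, 3, 3)) * 0.5, np.eye(4), "K1")
        cbf = k1_to_cbf(m, 0.65)
        back = cbf.data * 0.65 / 100.0
        assert np.max(np.abs(back - m.data) / np.maximum(m.data, 1e-30)) < 1e-12
        assert k1_to_cbf(ParametricMap(np.zeros((2, 2, 2)), np.eye(4), "K1")).data.max() == 0

    def test_invalid_extraction_rejected(self):
        m = ParametricMap(np.zeros((2, 2, 2)), np.eye(4), "K1")
        with pytest.raises(ValueError):
            k1_to_cbf(m, 0.0)


class TestCbfImage:
    def test_noise_free_regional_recovery(self, ctl_phantom, ctl_spec):
        """Regional mean CBF on the noise-free phantom reproduces the
        generating group values within 2%."""
        from pibflow.input_function import (
            correct_dispersion, early_average, extract_idif_mask, idif_tac,
        )
        from pibflow.region_stats import regional_means

        dyn, truth = ctl_phantom
        parc = truth.parcellation
        mask = extract_idif_mask(early_average(dyn), parc, label=parc.label_of("artery"))
        cp = correct_dispersion(idif_tac(dyn, mask))
        brain = (parc.labels > 0) & (parc.labels != parc.label_of("artery"))
        res = cbf_image(dyn, cp, brain_mask=brain)
        table = regional_means(res.cbf_map, parc)
        for _, row in table.iterrows():
            suffix = {"right": "_r", "left": "_l", "both": ""}[row["hemisphere"]]
            name = row["region"] + suffix
            if name == "artery":
                continue
            assert row["value"] == pytest.approx(ctl_spec.region_cbf[name], rel=0.02)

    def test_artery_excluded_by_mask(self, ctl_phantom):
        from pibflow.input_function import correct_dispersion, idif_tac

        dyn, truth = ctl_phantom
        parc = truth.parcellation
        artery = parc.labels == parc.label_of("artery")
        cp = correct_dispersion(idif_tac(dyn, [tuple(np.argwhere(artery)[0])]))
        res = cbf_image(dyn, cp, brain_mask=~artery & (parc.labels > 0))
        assert np.all(res.cbf_map.data[artery] == 0.0)

    def test_noisy_regional_bias_under_five_percent(self, schedule):
        """With frame-duration-scaled noise, regional CBF bias stays below
        5% when averaging over a few hundred voxels per region."""
        import pibflow.phantom as ph
        from pibflow.region_stats import regional_means

        spec = ph.default_phantom_spec(grid_shape=(14, 14, 14), noise_scale=0.3, seed=21)
        dyn, truth = ph.make_dynamic_pet(spec, schedule)
        parc = truth.parcellation
        brain = (parc.labels > 0) & (parc.labels != parc.label_of("artery"))
        res = cbf_image(dyn, truth.true_input, brain_mask=brain)
        table = regional_means(res.cbf_map, parc)
        for _, row in table.iterrows():
            suffix = {"right": "_r", "left": "_l", "both": ""}[row["hemisphere"]]
            name = row["region"] + suffix
            if name == "artery" or row["n_voxels"] < 100:
                continue
            assert abs(row["value"] - spec.region_cbf[name]) / spec.region_cbf[name] < 0.05
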