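import numpy as np
import pytest
from scipy.integrate import solve_ivp

from pibflow import phantom as ph
from pibflow._ode import disperse
from pibflow.io_core import FrameSchedule


def analytic_linear_segment(t, ta, ya, xa, m, tau):
    """Closed-form response of y' = (x - y)/tau to x(t) = xa + m (t - ta)."""
    x = xa + m * (t - ta)
    return (ya - xa + m * tau) * np.exp(-(t - ta) / tau) + x - m * tau


class TestDispersion:
    def test_zero_tau_is_identity(self):
        x = np.sin(np.linspace(0, 3, 50)) ** 2
        assert np.array_equal(disperse(x, 0.5, 0.0), x)

    def test_smoothing_delays_and_lowers_peak(self, gamma_input):
        undisp, disp = gamma_input
        assert disp.whole_blood.max() < undisp.whole_blood.max()
        assert (
            disp.times[np.argmax(disp.whole_blood)]
            > undisp.times[np.argmax(undisp.whole_blood)]
        )

    def test_matches_closed_form_convolution_of_pulse(self):
        """A piecewise-linear pulse dispersed through the exponential kernel
        must match the segment-wise closed-form solution to float precision
        (the propagator is exact for piecewise-linear inputs)."""
        dt, tau, h = 0.5, 4.0, 10.0
        t = np.arange(0.0, 80.0 + dt / 2, dt)
        # trapezoidal pulse: up-ramp 10-11 s, flat to 40 s, down-ramp 40-41 s
        x = np.interp(t, [0, 10, 11, 40, 41, 80], [0, 0, h, h, 0, 0])
        got = disperse(x, dt, tau)

        expected = np.empty_like(t)
        breaks = [0.0, 10.0, 11.0, 40.0, 41.0, 80.0]
        xs = [0.0, 0.0, h, h, 0.0, 0.0]
        y = 0.0
        for ta, tb, xa, xb in zip(breaks[:-1], breaks[1:], xs[:-1], xs[1:]):
            m = (xb - xa) / (tb - ta)
            seg = (t >= ta - 1e-12) & (t <= tb + 1e-12)
            expected[seg] = analytic_linear_segment(t[seg], ta, y, xa, m, tau)
            y = analytic_linear_segment(np.array([tb]), ta, y, xa, m, tau)[0]
        assert np.max(np.abs(got - expected)) < 1e-8


class TestInputFunction:
    def test_plasma_is_fixed_fraction(self, gamma_input):
        undisp, disp = gamma_input
        for f in (undisp, disp):
            assert np.allclose(f.plasma, 0.95 * f.whole_blood, rtol=0, atol=0)

    def test_peak_location_and_height(self):
        undisp, _ = ph.make_input_function(peak_time=25.0, peak_value=80.0, tau=0.0)
        i = np.argmax(undisp.whole_blood)
        assert undisp.times[i] == pytest.approx(25.0, abs=0.3)
        assert undisp.whole_blood[i] == pytest.approx(80.0, rel=1e-6)

    def test_invalid_args_rejected(self):
        with pytest.raises(ValueError):
            ph.make_input_function(peak_time=2.0, onset=5.0)
        with pytest.raises(ValueError):
            ph.make_input_function(dt=1.5)


class TestDynamicPhantom:
    def test_short_schedule_rejected(self, ctl_spec):
        short = FrameSchedule(np.array([0.0]), np.array([60.0]))
        with pytest.raises(ValueError, match="180"):
            ph.make_dynamic_pet(ctl_spec, short)

    def test_ground_truth_k1_from_frontal_cbf(self, ctl_phantom):
        """Right-frontal control CBF of 41.6 mL/min/100 g with E = 0.65
        gives K1 = 0.65 x 41.6/100 = 0.2704 1/min."""
        dyn, truth = ctl_phantom
        parc = truth.parcellation
        vals = truth.true_k1_map.data[parc.labels == parc.label_of("frontal_r")]
        assert np.allclose(vals, 0.2704)

    def test_k1_cbf_ratio_everywhere(self, ctl_phantom):
        _, truth = ctl_phantom
        tissue = truth.true_cbf_map.data > 0
        ratio = truth.true_k1_map.data[tissue] / truth.true_cbf_map.data[tissue]
        assert np.allclose(ratio, 0.65 / 100.0, rtol=1e-12)

    def test_noise_free_tac_matches_ode_oracle(self, ctl_phantom, ctl_spec, schedule):
        """Frame means of a tissue region agree with an independent stiff
        ODE integration of dC/dt = K1 Cp - k2 C within 0.1%."""
        dyn, truth = ctl_phantom
        parc = truth.parcellation
        voxel = np.argwhere(parc.labels == parc.label_of("parietal_l"))[0]
        tac = dyn.data[tuple(voxel)]

        k1 = 0.65 * ctl_spec.region_cbf["parietal_l"] / 100.0
        k2 = ctl_spec.k2_per_region["parietal_l"]
        cp_t = truth.true_input.times
        cp_v = truth.true_input.plasma

        def rhs(t, y):
            return (k1 / 60.0) * np.interp(t, cp_t, cp_v) - (k2 / 60.0) * y[0]

        sol = solve_ivp(rhs, (0, schedule.total_duration), [0.0],
                        rtol=1e-10, atol=1e-12, dense_output=True, max_step=5.0)
        fine = np.arange(0.0, schedule.total_duration + 0.025, 0.05)
        c = sol.sol(fine)[0]
        from scipy.integrate import cumulative_trapezoid

        cum = np.concatenate([[0.0], cumulative_trapezoid(c, fine)])
        means = (np.interp(schedule.ends, fine, cum) - np.interp(schedule.starts, fine, cum)) / schedule.durations
        rel = np.abs(tac - means) / means.max()
        assert rel.max() < 1e-3

    def test_artery_carries_dispersed_input(self, ctl_phantom):
        dyn, truth = ctl_phantom
        parc = truth.parcellation
        voxel = np.argwhere(parc.labels == parc.label_of("artery"))[0]
        tac = dyn.data[tuple(voxel)][:21]
        mids = dyn.schedule.mid_times[:21]
        expected = truth.true_input_dispersed.sample_whole_blood(mids)
        # frame means track mid-time samples of the smooth dispersed bolus
        assert np.max(np.abs(tac - expected)) / expected.max() < 0.02

    def test_seed_determinism(self, schedule):
        spec = ph.default_phantom_spec(grid_shape=(12, 12, 12), noise_scale=0.5, seed=3)
        d1, _ = ph.make_dynamic_pet(spec, schedule)
        d2, _ = ph.make_dynamic_pet(spec, schedule)
        assert np.array_equal(d1.data, d2.data)

    def test_noise_sd_scales_with_frame_duration(self, schedule):
        """Residual SD tracks noise_scale * sqrt(C/frame duration)."""
        spec0 = ph.default_phantom_spec(grid_shape=(12, 12, 12), noise_scale=0.0, seed=5)
        spec1 = ph.default_phantom_spec(grid_shape=(12, 12, 12), noise_scale=1.0, seed=5)
        clean, truth = ph.make_dynamic_pet(spec0, schedule)
        noisy, _ = ph.make_dynamic_pet(spec1, schedule)
        resid = noisy.data - clean.data
        wm = truth.parcellation.labels == 11
        # late 10-min frame of white matter: plenty of voxels, stable mean
        c = clean.data[wm][:, -1].mean()
        expected_sd = np.sqrt(c / 600.0)
        assert resid[wm][:, -1].std() == pytest.approx(expected_sd, rel=0.15)


class TestPhantomSpecValidation:
    def test_requires_artery_and_cerebellum(self):
        spec = ph.default_phantom_spec()
        labels = {k: v for k, v in spec.region_labels.items() if v != "artery"}
        with pytest.raises(ValueError, match="artery"):
            ph.PhantomSpec(region_labels=labels,
                           region_cbf=spec.region_cbf,
                           region_suvr=spec.region_suvr,
                           k2_per_region=spec.k2_per_region)

    def test_rejects_nonpositive_cbf(self):
        spec = ph.default_phantom_spec()
        bad = dict(spec.region_cbf, frontal_r=0.0)
        with pytest.raises(ValueError, match="CBF"):
            ph.PhantomSpec(region_labels=spec.region_labels, region_cbf=bad,
                           region_suvr=spec.region_suvr,
                           k2_per_region=spec.k2_per_region)


class TestBoldSeries:
    def test_shape_matches_acquisition(self):
        b = ph.make_bold_series(grid_shape=(4, 4, 4), n_volumes=201, tr=2.3, seed=0)
        assert b.data.shape == (4, 4, 4, 201)

    def test_pure_sinusoid_target_is_one(self):
        b = ph.make_bold_series(grid_shape=(3, 3, 3), broadband_amp=0.0, seed=1)
        assert np.all(b.target_falff > 0.95)

    def test_pure_noise_target_is_band_share(self):
        """With no sinusoids the expected amplitude spectrum is flat, so the
        target fALFF is the band's share of positive-frequency bins."""
        n, tr = 200, 2.0
        b = ph.make_bold_series(grid_shape=(3, 3, 3), n_volumes=n, tr=tr,
                                low_freq_amp=0.0, broadband_amp=1.0, seed=2)
        freqs = np.fft.rfftfreq(n, tr)
        pos = freqs > 0
        share = ((freqs >= 0.01) & (freqs <= 0.08) & pos).sum() / pos.sum()
        assert np.allclose(b.target_falff, share)

    @pytest.mark.parametrize("kwargs", [dict(n_volumes=10), dict(tr=0.0)])
    def test_invalid_args_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ph.make_bold_series(grid_shape=(3, 3, 3), **kwargs)

    def test_seed_determinism(self):
        a = ph.make_bold_series(grid_shape=(3, 3, 3), seed=9)
        b = ph.make_bold_series(grid_shape=(3, 3, 3), seed=9)
        assert np.array_equal(a.data, b.data)


class TestCohort:
    def test_sizes_and_domains(self):
        subjects, regional, extras = ph.generate_cohort(n_ad=27, n_ctl=16, seed=4)
        assert sum(s.group == "AD" for s in subjects) == 27
        assert sum(s.group == "CTL" for s in subjects) == 16
        assert all(s.visual_score in (0, 1, 2, 3) for s in subjects)
        assert all(0 <= s.mmse <= 30 for s in subjects)
        assert set(regional["quantity"]) == {"CBF", "SUVr"}
        # one value per (subject, region, hemisphere, quantity)
        assert not regional.duplicated(["subject", "region", "hemisphere", "quantity"]).any()

    def test_ad_group_shows_higher_cortical_uptake(self):
        _, regional, extras = ph.generate_cohort(seed=4)
        suvr = regional[(regional["quantity"] == "SUVr")
                        & regional["region"].isin(ph.LOBES)]
        merged = suvr.merge(extras[["subject", "group"]], on="subject")
        means = merged.groupby("group")["value"].mean()
        assert means["AD"] > means["CTL"] + 0.3
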