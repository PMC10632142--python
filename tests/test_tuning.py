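"""Direction-selectivity statistics: vector sums, DSI, von Mises fits, tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import comb

from retinads import imaging, synth, tuning

DIRS8 = np.arange(0.0, 360.0, 45.0)


def brute_force_vector_sum(directions, amplitudes):
    """Independent oracle: complex sum of clipped amplitudes."""
    z = sum(
        max(r, 0.0) * complex(math.cos(math.radians(d)), math.sin(math.radians(d)))
        for d, r in zip(directions, amplitudes)
    )
    total = sum(max(r, 0.0) for r in amplitudes)
    return abs(z), math.degrees(math.atan2(z.imag, z.real)) % 360.0, abs(z) / total if total else 0.0


class TestVectorSum:
    def test_uniform_responses_give_zero_nvs(self):
        vs = tuning.vector_sum(DIRS8, np.full(8, 0.7))
        assert vs.nvs == pytest.approx(0.0, abs=1e-12)

    def test_single_direction_gives_nvs_one(self):
        amps = np.zeros(8)
        amps[2] = 1.3  # 90 degrees
        vs = tuning.vector_sum(DIRS8, amps)
        assert vs.nvs == pytest.approx(1.0)
        assert vs.angle_deg == pytest.approx(90.0)

    def test_hand_computed_case_matches_oracle(self):
        amps = [2, 1, 1, 1, 1, 1, 1, 1]
        vs = tuning.vector_sum(DIRS8, amps)
        assert vs.nvs == pytest.approx(1.0 / 9.0)
        assert vs.angle_deg == pytest.approx(0.0, abs=1e-9)
        mag, ang, nvs = brute_force_vector_sum(DIRS8, amps)
        assert vs.magnitude == pytest.approx(mag)
        assert vs.nvs == pytest.approx(nvs)

    def test_all_zero_flags_angle_undefined(self):
        vs = tuning.vector_sum(DIRS8, np.zeros(8))
        assert vs.nvs == 0.0 and not vs.angle_defined

    def test_fewer_than_two_directions_rejected(self):
        with pytest.raises(ValueError, match="2 distinct"):
            tuning.vector_sum([90.0], [1.0])

    @given(
        st.lists(
            st.floats(min_value=-5, max_value=5, allow_nan=False), min_size=8, max_size=8
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_nvs_bounded_and_matches_oracle(self, amps):
        vs = tuning.vector_sum(DIRS8, amps)
        assert 0.0 <= vs.nvs <= 1.0 + 1e-12
        _, _, nvs = brute_force_vector_sum(DIRS8, amps)
        assert vs.nvs == pytest.approx(nvs, abs=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        amps = rng.random(8)
        a = tuning.vector_sum(DIRS8, amps)
        b = tuning.vector_sum(DIRS8, 13.7 * amps)
        assert a.nvs == pytest.approx(b.nvs)
        assert a.angle_deg == pytest.approx(b.angle_deg)


class TestDsi:
    @pytest.mark.parametrize(
        "pref,null,expected",
        [(0.4, 0.4, 0.0), (0.8, 0.0, 1.0), (1.0, 3.0, -0.5)],
    )
    def test_formula(self, pref, null, expected):
        assert tuning.dsi(pref, null) == pytest.approx(expected)

    def test_undefined_when_sum_zero(self):
        assert math.isnan(tuning.dsi(0.0, 0.0))

    def test_scale_invariance(self):
        assert tuning.dsi(0.9, 0.3) == pytest.approx(tuning.dsi(9.0, 3.0))

    def test_fixed_axis_allows_negative_post_drug_dsi(self):
        # pre-drug preference at 0 deg; post-drug response flipped to 180
        post = tuning.von_mises(DIRS8, 1.0, 180.0, 3.0)
        assert tuning.dsi_from_profile(DIRS8, post, pref_deg=0.0) < -0.9


class TestVonMisesFit:
    def test_model_peaks_at_mu_for_any_kappa(self):
        for kappa in (0.0, 0.5, 3.0, 20.0):
            assert tuning.von_mises(123.0, 2.5, 123.0, kappa) == pytest.approx(2.5)

    def test_exact_recovery_on_model_data(self):
        amps = tuning.von_mises(DIRS8, 1.0, 90.0, 2.0)
        fit = tuning.fit_von_mises(DIRS8, amps)
        assert fit.fit_ok
        assert fit.r_max == pytest.approx(1.0, rel=0.01)
        assert fit.mu_deg == pytest.approx(90.0, abs=0.9)
        assert fit.kappa == pytest.approx(2.0, rel=0.01)

    def test_constant_data_degenerates_to_kappa_zero(self):
        fit = tuning.fit_von_mises(DIRS8, np.full(8, 0.42))
        assert fit.kappa == pytest.approx(0.0, abs=1e-3)
        assert fit.r_max == pytest.approx(0.42, rel=1e-3)

    def test_too_few_directions_rejected(self):
        with pytest.raises(ValueError, match="4 directions"):
            tuning.fit_von_mises([0, 90, 180], [1, 2, 1])

    def test_vector_angle_matches_mu_across_kappa(self):
        """Vector-sum angle tracks the model's preferred direction within 5°."""
        for kappa in (0.5, 1, 2, 4, 8):
            amps = tuning.von_mises(DIRS8, 1.0, 77.0, kappa)
            vs = tuning.vector_sum(DIRS8, amps)
            assert abs((vs.angle_deg - 77.0 + 180) % 360 - 180) < 5.0


class TestResponsiveness:
    def test_exact_threshold_is_not_responsive(self):
        assert tuning.is_responsive(1.5 * 0.2, baseline_sd=0.2) is False

    def test_strongly_responsive(self):
        assert tuning.is_responsive(10 * 0.2, baseline_sd=0.2) is True

    def test_flat_trace_not_responsive(self):
        assert tuning.is_responsive(0.0, baseline_sd=0.2) is False

    def test_zero_baseline_sd_rejected(self):
        with pytest.raises(ValueError):
            tuning.is_responsive(1.0, baseline_sd=0.0)


class TestOrientation:
    def test_identity_convention(self):
        conv = tuning.OrientationConvention()
        assert np.allclose(conv.apply(DIRS8), DIRS8)

    def test_horizontal_flip_swaps_90_and_270(self):
        conv = tuning.OrientationConvention(flip=True)
        out = conv.apply([0.0, 90.0, 180.0, 270.0])
        assert np.allclose(out, [0.0, 270.0, 180.0, 90.0])

    @given(
        st.floats(min_value=0, max_value=359.9),
        st.floats(min_value=-360, max_value=360),
        st.booleans(),
    )
    @settings(max_examples=100, deadline=None)
    def test_roundtrip_is_identity(self, angle, rotation, flip):
        conv = tuning.OrientationConvention(rotation_deg=rotation, flip=flip)
        back = conv.invert(conv.apply(angle))
        assert float(back) == pytest.approx(angle % 360.0, abs=1e-6)


def _pulse_traces(speeds, amplitudes, fps=10.0):
    """Build a trace with one pulse per speed condition of the given amplitude."""
    epochs = []
    t = 30.0
    for trial in range(2):
        for s in speeds:
            epochs.append(synth.Epoch(0.0, s, t, t + 2.0, trial=trial))
            t += 7.0
    sch = synth.StimulusSchedule(tuple(epochs))
    n = int((t + 5) * fps)
    dff = np.zeros(n)
    times = np.arange(n) / fps
    for ep in epochs:
        amp = amplitudes[speeds.index(ep.speed_um_s)]
        sel = (times >= ep.t_on_s) & (times < ep.t_on_s + 1.5)
        dff[sel] = amp
    traces = imaging.RoiTraceSet(roi_ids=["roi_0"], raw_f=dff[None, :], frame_rate_hz=fps)
    traces.dff = dff[None, :]
    return traces, sch


class TestVelocityAndSpots:
    def test_flat_speed_profile_gives_flat_curve(self):
        speeds = [125.0, 250.0, 500.0, 1000.0, 2000.0]
        traces, sch = _pulse_traces(speeds, [0.5] * 5)
        table = tuning.velocity_tuning(traces, sch)
        assert table["peak_windowed_dff"].max() - table["peak_windowed_dff"].min() < 1e-9

    def test_bandpass_speed_profile_peak_recovered(self):
        speeds = [125.0, 250.0, 500.0, 1000.0, 2000.0]
        amps = [0.3, 1.0, 0.6, 0.3, 0.1]  # programmed peak at 250 µm/s
        traces, sch = _pulse_traces(speeds, amps)
        table = tuning.velocity_tuning(traces, sch)
        best = table.loc[table["peak_windowed_dff"].idxmax(), "speed_um_s"]
        assert best == 250.0

    def test_spot_integral_constant(self):
        # constant dff 0.5 over the 2-s spot -> integral 1.0
        fps = 50.0
        sch = synth.make_spot_schedule([100.0], pre_stimulus_s=30.0)
        n = int(40 * fps)
        times = np.arange(n) / fps
        dff = np.where((times >= 30.0) & (times <= 32.0), 0.5, 0.0)
        traces = imaging.RoiTraceSet(["roi_0"], dff[None, :], fps)
        traces.dff = dff[None, :]
        table = tuning.spot_response_integral(traces, sch)
        assert table["integral_dff_s"].iloc[0] == pytest.approx(1.0, rel=0.02)

    def test_spot_integral_triangle(self):
        # triangular pulse peaking at 1 over 2 s -> area 1.0 (closed form)
        fps = 100.0
        sch = synth.make_spot_schedule([200.0], pre_stimulus_s=30.0)
        n = int(40 * fps)
        times = np.arange(n) / fps
        dff = np.clip(1.0 - np.abs(times - 31.0), 0.0, None)
        traces = imaging.RoiTraceSet(["roi_0"], dff[None, :], fps)
        traces.dff = dff[None, :]
        table = tuning.spot_response_integral(traces, sch)
        assert table["integral_dff_s"].iloc[0] == pytest.approx(1.0, rel=0.01)

    def test_zero_trace_integrates_to_zero(self):
        fps = 50.0
        sch = synth.make_spot_schedule([100.0], pre_stimulus_s=30.0)
        dff = np.zeros(int(40 * fps))
        traces = imaging.RoiTraceSet(["roi_0"], dff[None, :], fps)
        traces.dff = dff[None, :]
        assert tuning.spot_response_integral(traces, sch)["integral_dff_s"].iloc[0] == 0.0


class TestGroupComparisons:
    def test_identical_groups_p_near_one(self):
        _, p = tuning.compare_groups([1, 2, 3, 4], [1, 2, 3, 4])
        assert p > 0.9

    def test_separated_groups_exact_p(self):
        """Fully separated n=8 vs 8: exact p = 2 / C(16, 8) by enumeration."""
        a = np.arange(1, 9, dtype=float)
        b = a + 100.0
        _, p = tuning.compare_groups(a, b)
        expected = 2.0 / comb(16, 8, exact=True)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_paired_identical_degenerate(self):
        with pytest.warns(UserWarning, match="zero"):
            _, p = tuning.compare_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            tuning.compare_groups([], [1.0])


class TestParameterRecoveryAtSnr5:
    def test_mu_within_10deg_and_nvs_monotone_in_kappa(self):
        """Movies at peak SNR ~5: fitted mu within 10° of truth and NVS
        increasing with tuning width kappa (Spearman rho > 0.9)."""
        kappas = [0.25, 0.5, 1.0, 2.0, 4.0, 8.0]
        nvss = []
        field = (48.0, 48.0)
        sch = synth.make_bar_schedule(
            n_trials=3, pre_stimulus_s=25.0, travel_um=float(np.hypot(*field)), seed=5
        )
        for i, kappa in enumerate(kappas):
            cell = synth.GroundTruthCell(
                center_xy_um=(24.0, 24.0), r_max=1.0, mu_deg=135.0, kappa=kappa,
                baseline_f0=100.0,
            )
            per_seed_nvs = []
            for rep in range(3):  # average NVS over noise realisations
                bundle = synth.generate_movie(
                    field, 1.0, 4.0, [cell], sch, noise_sd=20.0, seed=10 + 3 * i + rep
                )
                traces = imaging.compute_dff(
                    imaging.extract_traces(bundle.movie, bundle.soma_masks()), sch
                )
                resp = imaging.epoch_responses(traces, sch)
                means = resp.groupby("direction_deg")["peak_dff"].mean()
                if rep == 0:
                    fit = tuning.fit_von_mises(
                        means.index.to_numpy(), np.clip(means.to_numpy(), 0, None)
                    )
                    if kappa >= 1.0:  # mu weakly constrained for flat curves
                        assert abs((fit.mu_deg - 135.0 + 180) % 360 - 180) < 10.0
                per_seed_nvs.append(
                    tuning.vector_sum(means.index.to_numpy(), means.to_numpy()).nvs
                )
            nvss.append(np.mean(per_seed_nvs))
        rho = stats.spearmanr(kappas, nvss).statistic
        assert rho > 0.9
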