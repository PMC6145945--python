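"""Kinetic Monte Carlo generator: dwell draws, event statistics, rendering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chimotor.simulate import (
    SimConfig,
    render_noisy_trajectory,
    sample_dwell,
    simulate_step_sequence,
    simulate_trajectory,
    synth_kinetics_dataset,
    synth_spot_stack,
)


class TestSampleDwell:
    @pytest.mark.parametrize(
        "k, r, expected_s",
        [
            (100.0, np.exp(-1), 0.010),      # ln(1/e^-1)/100 = 10 ms
            (345.0, np.exp(-1), 1 / 345.0),  # the catalysis rate: 2.899 ms
            (50.0, 1.0, 0.0),                # ln(1) = 0
        ],
    )
    def test_closed_form(self, k, r, expected_s):
        assert sample_dwell(k, r) == pytest.approx(expected_s, rel=1e-12)

    @pytest.mark.parametrize("k, r", [(0.0, 0.5), (-3.0, 0.5), (10.0, 0.0), (10.0, 1.5)])
    def test_rejects_invalid_input(self, k, r):
        with pytest.raises(ValueError):
            sample_dwell(k, r)

    @given(st.floats(1e-3, 1e4), st.floats(1e-12, 1.0, exclude_min=True))
    @settings(derandomize=True, max_examples=50)
    def test_positive_and_scales_inversely_with_rate(self, k, r):
        d = sample_dwell(k, r)
        assert d >= 0
        assert sample_dwell(2 * k, r) == pytest.approx(d / 2, rel=1e-9)


class TestStepSequence:
    def test_forward_only_is_monotone_with_correct_mean_dwell(self):
        tau = 20.0  # ms
        cfg = SimConfig(
            step_ratios={"forward": 1.0, "double": 0.0, "backward": 0.0},
            dwell_taus_ms={"forward1": (tau,), "forward2": (26.0,),
                           "backward": (18.3,), "recovery": (17.1,)},
            n_events=2000,
            rng_seed=0,
        )
        ideal = simulate_step_sequence(cfg)
        steps = np.diff(ideal.levels_nm)
        assert np.all(steps == pytest.approx(1.1))
        dwells = np.array([e.dwell_ms for e in ideal.events])
        se = tau / np.sqrt(len(dwells))
        assert abs(dwells.mean() - tau) < 3 * se

    def test_recovery_always_follows_backward(self):
        cfg = SimConfig(
            step_ratios={"forward": 0.0, "double": 0.0, "backward": 1.0},
            n_events=200,
            rng_seed=1,
        )
        ideal = simulate_step_sequence(cfg)
        kinds = [e.kind for e in ideal.events]
        assert kinds[0::2] == ["backward"] * len(kinds[0::2])
        assert kinds[1::2] == ["recovery"] * len(kinds[1::2])
        # net displacement of each pair is zero
        assert ideal.levels_nm[-1] == pytest.approx(
            0.0 if len(kinds) % 2 == 0 else -1.1
        )

    def test_zero_events_gives_empty_sequence(self):
        cfg = SimConfig(n_events=0, rng_seed=0)
        ideal = simulate_step_sequence(cfg)
        assert ideal.events == []
        assert len(ideal.levels_nm) == 1

    def test_kind_frequencies_match_ratios(self):
        cfg = SimConfig(n_events=6000, rng_seed=2)
        ideal = simulate_step_sequence(cfg)
        kinds = np.array([e.kind for e in ideal.events])
        drawn = kinds[kinds != "recovery"]  # recovery is forced, not drawn
        for kind, p in (("forward1", 0.693), ("forward2", 0.142), ("backward", 0.165)):
            frac = np.mean(drawn == kind)
            se = np.sqrt(p * (1 - p) / len(drawn))
            assert abs(frac - p) < 4 * se

    def test_net_displacement_identity(self):
        cfg = SimConfig(n_events=500, rng_seed=3)
        ideal = simulate_step_sequence(cfg)
        kinds = [e.kind for e in ideal.events]
        expect = (
            kinds.count("forward1") * 1.1
            + kinds.count("forward2") * 2.2
            - kinds.count("backward") * 1.1
            + kinds.count("recovery") * 1.1
        )
        assert ideal.levels_nm[-1] == pytest.approx(expect, abs=1e-9)

    def test_convolution_dwell_mean_is_sum_of_taus(self):
        cfg = SimConfig(
            step_ratios={"forward": 1.0, "double": 0.0, "backward": 0.0},
            n_events=4000,
            rng_seed=4,
        )
        ideal = simulate_step_sequence(cfg)
        dwells = np.array([e.dwell_ms for e in ideal.events])
        expect = 2.9 + 23.9
        se = dwells.std() / np.sqrt(len(dwells))
        assert abs(dwells.mean() - expect) < 3 * se

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(step_ratios={"forward": 0.9, "double": 0.2, "backward": 0.1},
                      n_events=1).validate()
        with pytest.raises(ValueError):
            SimConfig(frame_interval_ms=0.0, n_events=1).validate()
        with pytest.raises(ValueError):
            SimConfig().validate()  # neither n_events nor duration


class TestRendering:
    def test_zero_noise_reproduces_ideal_staircase(self):
        cfg = SimConfig(n_events=20, rng_seed=5,
                        precision_peak_nm=1e-9, precision_spread_nm=0.0,
                        precision_floor_nm=0.0)
        rng = cfg.rng()
        ideal = simulate_step_sequence(cfg, rng)
        traj = render_noisy_trajectory(ideal, cfg, rng)
        assert np.allclose(traj.x_nm, ideal.position_at(traj.t_ms), atol=1e-6)

    def test_frame_count_matches_sampling(self):
        cfg = SimConfig(duration_ms=1000.0, n_events=None, tail_ms=0.0, rng_seed=6,
                        step_ratios={"forward": 1.0, "double": 0.0, "backward": 0.0})
        rng = cfg.rng()
        ideal = simulate_step_sequence(cfg, rng)
        traj = render_noisy_trajectory(ideal, cfg, rng)
        # 0.5 ms sampling over >=1 s of events -> >=2000 frames
        assert len(traj) == int(ideal.duration_ms / 0.5) + 1

    def test_pause_noise_sd_matches_configured(self):
        cfg = SimConfig(
            step_ratios={"forward": 1.0, "double": 0.0, "backward": 0.0},
            dwell_taus_ms={"forward1": (2000.0,), "forward2": (26.0,),
                           "backward": (18.3,), "recovery": (17.1,)},
            n_events=1, rng_seed=7, tail_ms=0.0,
            precision_peak_nm=0.34, precision_spread_nm=0.0, precision_floor_nm=0.0,
        )
        rng = cfg.rng()
        ideal = simulate_step_sequence(cfg, rng)
        traj = render_noisy_trajectory(ideal, cfg, rng)
        pause = traj.x_nm[traj.t_ms < ideal.breakpoints_ms[0]]
        assert len(pause) > 2000
        assert np.std(pause) == pytest.approx(0.34, rel=0.05)

    def test_bit_identical_under_fixed_seed(self):
        a = simulate_trajectory(SimConfig(n_events=50, rng_seed=11))
        b = simulate_trajectory(SimConfig(n_events=50, rng_seed=11))
        assert np.array_equal(a.x_nm, b.x_nm) and np.array_equal(a.y_nm, b.y_nm)


class TestSpotStack:
    def test_noiseless_centroid_matches_track(self):
        from chimotor.trajectory import RawTrajectory

        tr = RawTrajectory(t_ms=np.arange(2) * 0.5, x_nm=np.array([30.0, 30.0]),
                           y_nm=np.array([-20.0, -20.0]))
        stack = synth_spot_stack(tr, photons=5e4, shot_noise=False)
        img = stack[0].astype(float) - 40.0  # remove background
        yy, xx = np.mgrid[0:24, 0:24]
        cx = (xx * img).sum() / img.sum() * 66.7
        cy = (yy * img).sum() / img.sum() * 66.7
        assert cx - (23 / 2 * 66.7) == pytest.approx(30.0, abs=0.5)
        assert cy - (23 / 2 * 66.7) == pytest.approx(-20.0, abs=0.5)

    def test_zero_photons_gives_background_only(self):
        from chimotor.trajectory import RawTrajectory

        tr = RawTrajectory(t_ms=[0.0], x_nm=[0.0], y_nm=[0.0])
        stack = synth_spot_stack(tr, photons=0.0, shot_noise=False, background=40.0)
        assert np.all(stack == 40)

    def test_track_outside_field_rejected(self):
        from chimotor.trajectory import RawTrajectory

        tr = RawTrajectory(t_ms=[0.0], x_nm=[5000.0], y_nm=[0.0])
        with pytest.raises(ValueError):
            synth_spot_stack(tr)


class TestKineticsDataset:
    def test_hand_evaluated_rate(self):
        df = synth_kinetics_dataset(10.0, 50.0, 1000.0, [100.0], noise_cv=0.0)
        assert df.rate_per_s.iloc[0] == pytest.approx(6.25)

    def test_curve_maximum_at_sqrt_km_ksi(self):
        km, ksi = 50.0, 1000.0
        s_star = np.sqrt(km * ksi)
        s = np.array([s_star * 0.8, s_star, s_star * 1.25])
        df = synth_kinetics_dataset(10.0, km, ksi, s, noise_cv=0.0)
        assert df.rate_per_s.idxmax() == 1

    def test_michaelis_menten_limit(self):
        df = synth_kinetics_dataset(10.0, 50.0, 1e12, [50.0], noise_cv=0.0)
        assert df.rate_per_s.iloc[0] == pytest.approx(5.0, rel=1e-9)
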