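"""Kinetic-scheme arithmetic, thermodynamics, velocity oracle and bulk kinetics."""

import numpy as np
import pytest

from chimotor.kinetics import SubstrateInhibitionModel, substrate_inhibition_rate
from chimotor.scheme import (
    KineticScheme,
    catalysis_probability,
    equilibrium_and_deltaG,
    equilibrium_from_rates,
    kie_ratio,
    mean_velocity,
    processivity,
)
from chimotor.simulate import SimConfig, simulate_step_sequence, synth_kinetics_dataset


@pytest.fixture()
def paper_scheme():
    """Scheme at the measured time constants of the processive cycle."""
    return KineticScheme(
        tau_cat_ms=2.9,
        tau_forward_long_ms=23.9,
        tau_dec_ms=17.1,
        tau_back_ms=18.3,
        tau_forward2_ms=26.0,
    )


class TestScheme:
    def test_release_time_constant(self, paper_scheme):
        assert paper_scheme.tau_release_ms == pytest.approx(6.8)

    def test_rates_at_reported_precision(self, paper_scheme):
        assert paper_scheme.k_cat == 345.0
        assert paper_scheme.k_back == 54.6
        assert paper_scheme.k_dec == 58.5

    def test_release_equal_to_recovery_gives_zero(self):
        s = KineticScheme(tau_cat_ms=2.9, tau_forward_long_ms=17.1,
                          tau_dec_ms=17.1, tau_back_ms=18.3)
        assert s.tau_release_ms == pytest.approx(0.0)
        assert not s.release_physical

    def test_catalysis_probability(self, paper_scheme):
        assert catalysis_probability(paper_scheme) == pytest.approx(86.3, abs=0.05)

    def test_catalysis_probability_limits(self):
        s = KineticScheme(tau_cat_ms=10.0, tau_forward_long_ms=20.0,
                          tau_dec_ms=15.0, tau_back_ms=10.0)
        assert catalysis_probability(s) == pytest.approx(50.0)

    def test_equilibrium_and_free_energy(self, paper_scheme):
        th = equilibrium_and_deltaG(paper_scheme)
        assert th.K_eq == pytest.approx(1.1)
        assert th.delta_G_kcal_mol == pytest.approx(-0.04, abs=0.005)

    def test_free_energy_closed_forms(self):
        th = equilibrium_from_rates(58.5, 58.5)
        assert th.delta_G_kcal_mol == pytest.approx(0.0, abs=1e-12)
        th_e = equilibrium_from_rates(np.e * 10.0, 10.0)
        assert th_e.delta_G_kcal_mol == pytest.approx(-0.592, abs=0.001)

    def test_free_energy_antisymmetric_in_K(self):
        a = equilibrium_from_rates(60.0, 40.0)
        b = equilibrium_from_rates(40.0, 60.0)
        assert a.delta_G_kcal_mol == pytest.approx(-b.delta_G_kcal_mol)


class TestMeanVelocity:
    def test_forward_only_closed_form(self):
        s = KineticScheme(tau_cat_ms=2.9, tau_forward_long_ms=23.9,
                          tau_dec_ms=17.1, tau_back_ms=18.3)
        # cycle = 2.9 + 6.8 + 17.1 = 26.8 ms per 1.04 nm
        assert mean_velocity(s) == pytest.approx(38.8, abs=0.05)

    def test_velocity_doubles_when_rates_double(self, paper_scheme):
        ratios = {"forward": 0.693, "double": 0.142, "backward": 0.165}
        fast = KineticScheme(
            tau_cat_ms=2.9 / 2, tau_forward_long_ms=23.9 / 2,
            tau_dec_ms=17.1 / 2, tau_back_ms=18.3 / 2, tau_forward2_ms=13.0,
        )
        assert mean_velocity(fast, ratios) == pytest.approx(
            2 * mean_velocity(paper_scheme, ratios), rel=1e-12
        )

    def test_matches_kmc_ensemble_within_3_se(self, paper_scheme):
        ratios = {"forward": 0.693, "double": 0.142, "backward": 0.165}
        v_expect = mean_velocity(paper_scheme, ratios, step_size_nm=1.1)
        vs = []
        for seed in range(30):
            cfg = SimConfig(n_events=400, rng_seed=1000 + seed)
            ideal = simulate_step_sequence(cfg)
            vs.append(ideal.levels_nm[-1] / ideal.duration_ms * 1000)
        vs = np.array(vs)
        se = vs.std(ddof=1) / np.sqrt(len(vs))
        assert abs(vs.mean() - v_expect) < 3 * se


class TestKIE:
    def test_time_constant_convention(self):
        assert kie_ratio(2.9, 10.1) == pytest.approx(3.48, abs=0.01)

    def test_rate_convention(self):
        assert kie_ratio(4.6, 2.0, quantity="rate") == pytest.approx(2.3)

    def test_no_isotope_effect(self):
        assert kie_ratio(5.0, 5.0) == 1.0

    def test_positive_values_required(self):
        with pytest.raises(ValueError):
            kie_ratio(-1.0, 2.0)


class TestProcessivity:
    def test_run_length_conversion(self):
        assert processivity(86.2) == 83
        assert processivity(1.04) == 1


class TestSubstrateInhibition:
    def test_exact_recovery_on_noiseless_curve(self):
        s = np.array([5, 10, 25, 50, 100, 200, 400, 540], dtype=float)
        v = substrate_inhibition_rate(s, 10.0, 50.0, 1000.0)
        fit = SubstrateInhibitionModel(s, v).fit()
        assert fit.kcat_per_s == pytest.approx(10.0, abs=1e-6)
        assert fit.km_uM == pytest.approx(50.0, abs=1e-5)
        assert fit.ksi_uM == pytest.approx(1000.0, rel=1e-5)

    def test_kcat_bias_small_under_noise(self):
        kcats = []
        for seed in range(100):
            df = synth_kinetics_dataset(
                10.0, 50.0, 1000.0, [5, 10, 25, 50, 100, 200, 400, 540],
                noise_cv=0.05, rng_seed=seed,
            )
            kcats.append(SubstrateInhibitionModel.from_dataframe(df).fit().kcat_per_s)
        assert np.mean(kcats) == pytest.approx(10.0, rel=0.02)

    def test_no_inhibition_reported_as_bound(self):
        s = np.array([5, 10, 25, 50, 100, 200], dtype=float)
        v = 10.0 * s / (50.0 + s)  # plain Michaelis-Menten
        fit = SubstrateInhibitionModel(s, v).fit()
        assert fit.ksi_at_bound
        assert fit.kcat_per_s == pytest.approx(10.0, rel=1e-3)
        assert fit.km_uM == pytest.approx(50.0, rel=1e-2)

    def test_minimum_design_enforced(self):
        with pytest.raises(ValueError):
            SubstrateInhibitionModel([1, 2, 3], [0.1, 0.2, 0.3])
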