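"""Step categorization rules and dwell-time distribution fits."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from chimotor.dwell import (
    ConvolvedExponentialDwellModel,
    SingleExponentialDwellModel,
    categorize_steps,
    fit_dwell_convolution_censored,
    fit_dwell_single_censored,
)


def events_df(sizes, trajectory=None):
    df = pd.DataFrame({"size_nm": sizes, "dwell_ms": np.full(len(sizes), 10.0)})
    if trajectory is not None:
        df.insert(0, "trajectory", trajectory)
    return df


class TestCategorize:
    @pytest.mark.parametrize(
        "sizes, expected",
        [
            ([1.1, -1.1, 1.1], ["uncategorized", "backward", "recovery"]),
            ([1.1, 2.5], ["uncategorized", "forward2"]),
            ([-1.1, -1.1], ["uncategorized", "backward_after_backward"]),
            ([1.1, 1.1, 1.9], ["uncategorized", "forward1", "forward1"]),
            ([1.1, 2.0], ["uncategorized", "forward1"]),  # 0-2 nm inclusive upper edge
        ],
    )
    def test_rules(self, sizes, expected):
        out = categorize_steps(events_df(sizes))
        assert out.category.tolist() == expected

    def test_categories_reset_per_trajectory(self):
        df = events_df([1.1, -1.1, 1.1, 1.1], trajectory=[0, 0, 1, 1])
        out = categorize_steps(df)
        assert out.category.tolist() == ["uncategorized", "backward",
                                         "uncategorized", "forward1"]

    def test_category_counts_follow_generator_ratios(self, default_pipeline_run):
        _, trajs, result = default_pipeline_run
        counts = result.step_table.category.value_counts()
        drawn = counts.get("forward1", 0) + counts.get("forward2", 0) + counts.get("backward", 0)
        frac_b = counts.get("backward", 0) / drawn
        se = np.sqrt(0.165 * 0.835 / drawn)
        # detection loses short-dwell backward/recovery pairs, so allow a
        # deficit of a few points beyond binomial error
        assert frac_b == pytest.approx(0.165, abs=0.05)
        assert frac_b > 0.08


class TestSingleExponentialFit:
    @pytest.mark.parametrize("tau", [18.3, 17.1, 26.0])
    def test_recovers_generator_tau(self, tau, rng):
        d = rng.exponential(tau, 2000)
        fit = SingleExponentialDwellModel(d, bin_width_ms=4.0).fit()
        assert fit.tau_ms[0] == pytest.approx(tau, rel=0.09)
        assert fit.tau_err_ms[0] < 1.5

    def test_all_dwells_in_excluded_bin_fails(self):
        d = np.full(100, 1.0)
        with pytest.raises(RuntimeError):
            SingleExponentialDwellModel(d, bin_width_ms=4.0).fit()

    def test_mle_equals_sample_mean(self, rng):
        d = rng.exponential(20.0, 500)
        fit = SingleExponentialDwellModel(d).fit(method="mle")
        assert fit.tau_ms[0] == pytest.approx(d.mean(), rel=1e-12)

    def test_censored_fit_unbiased_under_dead_time(self, rng):
        d = rng.exponential(17.1, 4000)
        kept = d[d > 3.0]  # hard detector dead time
        fit = fit_dwell_single_censored(kept, dead_time_ms=3.0)
        assert fit.tau_ms[0] == pytest.approx(17.1, rel=0.06)


class TestConvolutionFit:
    def test_recovers_both_time_constants(self, rng):
        d = rng.exponential(23.9, 3000) + rng.exponential(2.9, 3000)
        fit = ConvolvedExponentialDwellModel(d, bin_width_ms=2.0).fit()
        assert fit.tau_long_ms == pytest.approx(23.9, rel=0.15)
        assert fit.tau_short_ms == pytest.approx(2.9, rel=0.30)

    def test_heavy_water_regime_shifts_only_short_constant(self, rng):
        d = rng.exponential(23.9, 4000) + rng.exponential(10.1, 4000)
        fit = ConvolvedExponentialDwellModel(d, bin_width_ms=2.0).fit()
        assert fit.tau_long_ms == pytest.approx(23.9, rel=0.15)
        assert fit.tau_short_ms == pytest.approx(10.1, rel=0.20)

    def test_model_vanishes_when_rates_equal(self):
        from chimotor.dwell import _convolution_model

        x = np.linspace(0, 50, 100)
        assert np.allclose(_convolution_model(x, 5.0, 0.1, 0.1), 0.0)

    def test_taus_ordered_long_first(self, rng):
        d = rng.exponential(23.9, 2000) + rng.exponential(2.9, 2000)
        fit = ConvolvedExponentialDwellModel(d).fit()
        assert fit.tau_long_ms > fit.tau_short_ms

    def test_ls_fit_agrees_with_unbinned_mle_oracle(self, rng):
        """Binned LS vs an independent unbinned hypoexponential MLE."""
        d = rng.exponential(23.9, 5000) + rng.exponential(2.9, 5000)

        def nll(lp):
            tl, ts = np.exp(lp)
            f = (np.exp(-d / tl) - np.exp(-d / ts)) / (tl - ts)
            return -np.sum(np.log(np.maximum(f, 1e-300)))

        r = minimize(nll, x0=np.log([20.0, 4.0]), method="Nelder-Mead")
        tl_mle, ts_mle = np.sort(np.exp(r.x))[::-1]
        fit = ConvolvedExponentialDwellModel(d, bin_width_ms=2.0).fit()
        assert fit.tau_long_ms == pytest.approx(tl_mle, rel=0.10)
        assert fit.tau_short_ms == pytest.approx(ts_mle, rel=0.35)

    def test_censored_mle_corrects_dead_time(self, rng):
        d = rng.exponential(23.9, 6000) + rng.exponential(2.9, 6000)
        kept = d[d > 2.0]
        fit = fit_dwell_convolution_censored(kept, dead_time_ms=2.0)
        assert fit.tau_long_ms == pytest.approx(23.9, rel=0.10)
        assert fit.tau_short_ms == pytest.approx(2.9, rel=0.25)

    def test_negative_dwells_rejected(self):
        with pytest.raises(ValueError):
            ConvolvedExponentialDwellModel(np.array([-1.0, 2.0]))


def test_first_bin_exclusion_reduces_bias_under_censoring():
    """Exclusion shields the fit from a miscounted first bin.

    Detection cannot resolve the shortest pauses, so the first histogram
    bin of detected dwells is depleted; fitting it anyway drags both
    time constants away from truth, while dropping it leaves the fit on
    the undistorted part of the distribution.
    """
    wins = 0
    n_rep = 30
    for s in range(n_rep):
        g = np.random.default_rng(3000 + s)
        d = g.exponential(23.9, 3000) + g.exponential(2.9, 3000)
        d = d[d > 2.0]
        fe = ConvolvedExponentialDwellModel(d, 4.0, exclude_first_bin=True).fit()
        fi = ConvolvedExponentialDwellModel(d, 4.0, exclude_first_bin=False).fit()
        bias_e = abs(fe.tau_long_ms - 23.9) / 23.9 + abs(fe.tau_short_ms - 2.9) / 2.9
        bias_i = abs(fi.tau_long_ms - 23.9) / 23.9 + abs(fi.tau_short_ms - 2.9) / 2.9
        wins += bias_e < bias_i
    assert wins / n_rep >= 0.75
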