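"""Step categorization and dwell-time distribution fitting.

Detected steps are sorted into the four kinetic categories of the
processive cycle using the size of the step and the direction of the
*previous* step:

* ``forward1``  — forward step of 0–2 nm following a forward step;
* ``forward2``  — forward step larger than 2 nm following a forward step;
* ``backward``  — backward step following a forward step;
* ``recovery``  — forward step following a backward step;
* ``backward_after_backward`` — consecutive backward steps; too rare to
  fit and excluded from kinetics;
* ``uncategorized`` — the first step of a trajectory (no predecessor).

Dwell-time histograms are fitted by least squares.  Pauses before 1-nm
forward steps follow a consecutive two-state reaction, whose density is
the convolution of two exponentials,

    y = a * [exp(-b x) - exp(-c x)],

with a rise time set by the fast process and a decay by the slow one;
every other category follows a single exponential y = a exp(-b x).  The
first histogram bin is excluded by default: step detection over- and
under-counts very short dwells, and simulations show fits ignoring the
first bin recover the true time constants with less bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

CATEGORIES = (
    "forward1",
    "forward2",
    "backward",
    "recovery",
    "backward_after_backward",
    "uncategorized",
)

#: forward sizes in (0, 2] nm count as 1-nm steps; > 2 nm as 2-nm steps
FORWARD1_MAX_NM = 2.0


def categorize_steps(events: pd.DataFrame, group: Optional[str] = "trajectory") -> pd.DataFrame:
    """Assign kinetic categories from step size and previous direction.

    ``events`` must be time-ordered within each trajectory and contain a
    ``size_nm`` column; if a ``group`` column is present categories reset
    at each trajectory. Returns a copy with a ``category`` column.
    """
    df = events.copy()
    cats = np.full(len(df), "uncategorized", dtype=object)
    if group is not None and group in df.columns:
        groups = df.groupby(group, sort=False).indices.values()
    else:
        groups = [np.arange(len(df))]
    sizes = df["size_nm"].to_numpy()
    for idx in groups:
        idx = np.asarray(idx)
        for j in range(1, len(idx)):
            s = sizes[idx[j]]
            prev_forward = sizes[idx[j - 1]] > 0
            if s > 0 and prev_forward:
                cats[idx[j]] = "forward1" if s <= FORWARD1_MAX_NM else "forward2"
            elif s < 0 and prev_forward:
                cats[idx[j]] = "backward"
            elif s > 0 and not prev_forward:
                cats[idx[j]] = "recovery"
            else:
                cats[idx[j]] = "backward_after_backward"
    df["category"] = cats
    return df


def _binned_histogram(dwells: np.ndarray, bin_width_ms: float):
    upper = max(np.max(dwells), bin_width_ms) + bin_width_ms
    edges = np.arange(0.0, upper + bin_width_ms, bin_width_ms)
    counts, _ = np.histogram(dwells, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return edges, centers, counts.astype(float)


@dataclass
class DwellFitResults:
    """Fitted dwell-time distribution.

    ``params`` holds (a, b) or (a, b, c) with rates in 1/ms; ``bse`` the
    asymptotic standard errors. ``tau_ms``/``tau_err_ms`` give the time
    constants (ms), ordered long-first for the convolution model.
    """

    model: str                       # "single_exp" | "exp_convolution"
    params: np.ndarray
    bse: np.ndarray
    tau_ms: tuple
    tau_err_ms: tuple
    n: int
    bin_width_ms: float
    first_bin_excluded: bool
    method: str = "ls"
    degenerate: bool = False
    centers: Optional[np.ndarray] = None
    counts: Optional[np.ndarray] = None

    @property
    def tau_long_ms(self) -> float:
        return self.tau_ms[0]

    @property
    def tau_short_ms(self) -> float:
        if self.model != "exp_convolution":
            raise AttributeError("tau_short is defined for the convolution model only")
        return self.tau_ms[1]

    def predict(self, x_ms) -> np.ndarray:
        x = np.asarray(x_ms, dtype=float)
        if self.model == "single_exp":
            a, b = self.params
            return a * np.exp(-b * x)
        a, b, c = self.params
        return a * (np.exp(-b * x) - np.exp(-c * x))

    def summary(self) -> str:
        name = {"single_exp": "single exponential", "exp_convolution": "two-exponential convolution"}
        lines = [
            f"Dwell-time fit ({name[self.model]}, {self.method}, n={self.n})",
            f"  bin width {self.bin_width_ms:g} ms, first bin "
            + ("excluded" if self.first_bin_excluded else "included"),
        ]
        labels = ("tau_long", "tau_short") if self.model == "exp_convolution" else ("tau",)
        for lab, t, e in zip(labels, self.tau_ms, self.tau_err_ms):
            lines.append(f"  {lab:9s} = {t:6.1f} +/- {e:.1f} ms")
        if self.degenerate:
            lines.append("  WARNING: near-degenerate rates (b ~ c), fit unstable")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.bar(self.centers, self.counts, width=self.bin_width_ms * 0.9, alpha=0.5)
        xs = np.linspace(0, self.centers[-1], 300)
        ax.plot(xs, self.predict(xs), color="C0")
        ax.set_xlabel("dwell time (ms)")
        ax.set_ylabel("counts")
        return ax


class SingleExponentialDwellModel:
    """Least-squares fit of y = a exp(-b x) to a binned dwell histogram.

    Parameters
    ----------
    dwells_ms : array
        Dwell times in milliseconds (n >= 50 recommended).
    bin_width_ms : float
        Histogram bin width (default 4 ms).
    exclude_first_bin : bool
        Drop the first bin before fitting (default True; see module notes).
    weights : {"uniform", "poisson"}
        Uniform least squares or counting-noise weights sqrt(max(count,1)).
    """

    def __init__(
        self,
        dwells_ms,
        bin_width_ms: float = 4.0,
        exclude_first_bin: bool = True,
        weights: str = "uniform",
        exclude_bins: int | None = None,
    ) -> None:
        self.dwells = np.asarray(dwells_ms, dtype=float)
        if np.any(self.dwells < 0):
            raise ValueError("dwell times must be non-negative")
        self.bin_width_ms = bin_width_ms
        self.exclude_first_bin = exclude_first_bin
        self.weights = weights
        self.exclude_bins = (1 if exclude_first_bin else 0) if exclude_bins is None else exclude_bins

    def fit(self, method: str = "ls") -> DwellFitResults:
        if method == "mle":
            return self._fit_mle()
        edges, centers, counts = _binned_histogram(self.dwells, self.bin_width_ms)
        k = self.exclude_bins
        if k:
            edges, centers, counts = edges[k:], centers[k:], counts[k:]
        if np.sum(counts) == 0:
            raise RuntimeError("no data left to fit (all dwells in the excluded bin?)")
        sigma = np.sqrt(np.maximum(counts, 1.0)) if self.weights == "poisson" else None
        b0 = 1.0 / max(np.mean(self.dwells), 1e-6)
        a0 = max(counts.max(), 1.0) * np.exp(b0 * centers[0])
        # fit the bin-averaged model, not the centre value: exact for the
        # histogram expectation, removes discretization bias
        popt, pcov = curve_fit(
            lambda x, a, b: a * _exp_bin_mean(edges, b),
            centers,
            counts,
            p0=[a0, b0],
            sigma=sigma,
            bounds=([0.0, 1.0 / 500.0], [np.inf, 1.0 / 0.5]),
            maxfev=10000,
        )
        bse = np.sqrt(np.diag(pcov))
        tau = 1.0 / popt[1]
        tau_err = bse[1] / popt[1] ** 2
        return DwellFitResults(
            model="single_exp",
            params=popt,
            bse=bse,
            tau_ms=(tau,),
            tau_err_ms=(tau_err,),
            n=len(self.dwells),
            bin_width_ms=self.bin_width_ms,
            first_bin_excluded=self.exclude_first_bin,
            centers=centers,
            counts=counts,
        )

    def _fit_mle(self) -> DwellFitResults:
        # exponential MLE is the sample mean; SE = tau/sqrt(n)
        tau = float(np.mean(self.dwells))
        n = len(self.dwells)
        return DwellFitResults(
            model="single_exp",
            params=np.array([n, 1.0 / tau]),
            bse=np.array([np.nan, (1.0 / tau) / np.sqrt(n)]),
            tau_ms=(tau,),
            tau_err_ms=(tau / np.sqrt(n),),
            n=n,
            bin_width_ms=np.nan,
            first_bin_excluded=False,
            method="mle",
        )


def _convolution_model(x, a, b, c):
    return a * (np.exp(-b * x) - np.exp(-c * x))


def _exp_bin_mean(edges, rate):
    """Average of exp(-rate x) over each bin; exact, avoids centre bias."""
    x0, x1 = edges[:-1], edges[1:]
    return (np.exp(-rate * x0) - np.exp(-rate * x1)) / (rate * (x1 - x0))


class ConvolvedExponentialDwellModel:
    """Fit of the two-exponential convolution to a binned dwell histogram.

    The fitted form y = a [exp(-b x) - exp(-c x)] is symmetric under
    b <-> c (with a -> -a); the fit resolves the degeneracy by reporting
    time constants ordered long-first. Rates within 1% of each other are
    flagged near-degenerate (the model value vanishes at b = c).

    Default bin width is 2 ms, finer than for single-exponential fits:
    the fast time constant (~3 ms) is identified mostly by the histogram
    rise, which 4-ms bins with the first bin excluded cannot resolve.
    """

    def __init__(
        self,
        dwells_ms,
        bin_width_ms: float = 2.0,
        exclude_first_bin: bool = True,
        weights: str = "uniform",
        exclude_bins: int | None = None,
    ) -> None:
        self.dwells = np.asarray(dwells_ms, dtype=float)
        if np.any(self.dwells < 0):
            raise ValueError("dwell times must be non-negative")
        self.bin_width_ms = bin_width_ms
        self.exclude_first_bin = exclude_first_bin
        self.weights = weights
        self.exclude_bins = (1 if exclude_first_bin else 0) if exclude_bins is None else exclude_bins

    def fit(self, method: str = "ls") -> DwellFitResults:
        if method == "mle":
            return self._fit_mle()
        edges, centers, counts = _binned_histogram(self.dwells, self.bin_width_ms)
        k = self.exclude_bins
        if k:
            edges, centers, counts = edges[k:], centers[k:], counts[k:]
        if np.sum(counts) == 0:
            raise RuntimeError("no data left to fit (all dwells in the excluded bin?)")
        sigma = np.sqrt(np.maximum(counts, 1.0)) if self.weights == "poisson" else None
        mean = float(np.mean(self.dwells))
        t_peak = centers[np.argmax(counts)]
        tau_long0 = max(mean, 1.0)
        tau_short0 = min(max(0.4 * t_peak, 0.6), 0.8 * tau_long0)
        b0, c0 = 1.0 / tau_long0, 1.0 / tau_short0
        a0 = counts.max() / max(
            np.max(_convolution_model(centers, 1.0, b0, c0)), 1e-12
        )
        lo, hi = 1.0 / 500.0, 1.0 / 0.5
        # bin-averaged model expectation (see single-exponential fit)
        popt, pcov = curve_fit(
            lambda x, a, b, c: a * (_exp_bin_mean(edges, b) - _exp_bin_mean(edges, c)),
            centers,
            counts,
            p0=[a0, b0, c0],
            sigma=sigma,
            bounds=([0.0, lo, lo], [np.inf, hi, hi]),
            maxfev=20000,
        )
        bse = np.sqrt(np.diag(pcov))
        rates = np.array([popt[1], popt[2]])
        errs = np.array([bse[1], bse[2]])
        order = np.argsort(rates)  # slow rate first -> long tau first
        taus = 1.0 / rates[order]
        tau_errs = errs[order] / rates[order] ** 2
        degenerate = abs(rates[0] - rates[1]) < 0.01 * max(rates)
        return DwellFitResults(
            model="exp_convolution",
            params=popt,
            bse=bse,
            tau_ms=tuple(taus),
            tau_err_ms=tuple(tau_errs),
            n=len(self.dwells),
            bin_width_ms=self.bin_width_ms,
            first_bin_excluded=self.exclude_first_bin,
            degenerate=bool(degenerate),
            centers=centers,
            counts=counts,
        )

    def _fit_mle(self) -> DwellFitResults:
        """Unbinned maximum likelihood under the hypoexponential density."""
        from scipy.optimize import minimize

        t = self.dwells
        mean = float(np.mean(t))

        def nll(log_taus):
            tl, ts = np.exp(log_taus)
            if abs(tl - ts) < 1e-9:
                return 1e12
            f = (np.exp(-t / tl) - np.exp(-t / ts)) / (tl - ts)
            f = np.maximum(f, 1e-300)
            return -np.sum(np.log(f))

        res = minimize(
            nll, x0=np.log([max(mean, 1.0), max(0.15 * mean, 0.5)]), method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 4000},
        )
        tl, ts = np.sort(np.exp(res.x))[::-1]
        return DwellFitResults(
            model="exp_convolution",
            params=np.array([np.nan, 1.0 / tl, 1.0 / ts]),
            bse=np.full(3, np.nan),
            tau_ms=(tl, ts),
            tau_err_ms=(np.nan, np.nan),
            n=len(t),
            bin_width_ms=np.nan,
            first_bin_excluded=False,
            method="mle",
        )


def fit_dwell_convolution_censored(dwells_ms, dead_time_ms: float = 2.0) -> DwellFitResults:
    """Censoring-corrected MLE of the two-exponential convolution.

    The step detector cannot resolve pauses shorter than roughly its
    minimum plateau (the dead time), so the detected-dwell distribution
    is depleted at small times and a fit of the full density is biased.
    This estimator conditions the hypoexponential density on
    ``t > dead_time_ms`` (left truncation) and maximizes the unbinned
    likelihood of the surviving dwells, which restores both time
    constants when detection is essentially complete past the dead time.
    Standard errors come from the inverse observed information.
    """
    from scipy.optimize import minimize

    t_all = np.asarray(dwells_ms, dtype=float)
    t0 = float(dead_time_ms)
    t = t_all[t_all > t0]
    if len(t) < 100:
        raise ValueError("need at least 100 dwells beyond the dead time")

    def nll(log_taus):
        tl, ts = np.exp(log_taus)
        if abs(tl - ts) < 1e-9:
            return 1e12
        f = (np.exp(-t / tl) - np.exp(-t / ts)) / (tl - ts)
        surv = (tl * np.exp(-t0 / tl) - ts * np.exp(-t0 / ts)) / (tl - ts)
        return -np.sum(np.log(np.maximum(f, 1e-300))) + len(t) * np.log(max(surv, 1e-300))

    x0 = np.log([max(np.mean(t), 2.0), max(0.12 * np.mean(t), 0.8)])
    res = minimize(nll, x0=x0, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 5000})
    tl, ts = np.sort(np.exp(res.x))[::-1]
    # observed information via central differences on log-parameters
    errs = (np.nan, np.nan)
    try:
        h = 1e-4
        lp = np.log([tl, ts])
        H = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                pp = lp.copy(); pp[i] += h; pp[j] += h
                pm = lp.copy(); pm[i] += h; pm[j] -= h
                mp = lp.copy(); mp[i] -= h; mp[j] += h
                mm = lp.copy(); mm[i] -= h; mm[j] -= h
                H[i, j] = (nll(pp) - nll(pm) - nll(mp) + nll(mm)) / (4 * h * h)
        cov = np.linalg.inv(H)
        errs = (tl * np.sqrt(max(cov[0, 0], 0.0)), ts * np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        pass
    return DwellFitResults(
        model="exp_convolution",
        params=np.array([np.nan, 1.0 / tl, 1.0 / ts]),
        bse=np.full(3, np.nan),
        tau_ms=(float(tl), float(ts)),
        tau_err_ms=errs,
        n=len(t_all),
        bin_width_ms=np.nan,
        first_bin_excluded=False,
        method=f"mle_censored(t0={t0:g}ms)",
        degenerate=bool(abs(tl - ts) < 0.01 * tl),
    )


def fit_dwell_single_censored(dwells_ms, dead_time_ms: float = 3.0) -> DwellFitResults:
    """Censoring-corrected exponential fit: shifted mean of surviving dwells.

    For an exponential dwell left-truncated at the detector dead time the
    MLE of the time constant is ``mean(t | t > t0) - t0`` (memorylessness),
    insensitive to how detection depletes the shortest pauses.  Single-
    exponential categories flanked by two detected steps lose dwells over
    roughly twice the dead time of the convolution case, hence the larger
    default.
    """
    t_all = np.asarray(dwells_ms, dtype=float)
    t0 = float(dead_time_ms)
    t = t_all[t_all > t0]
    if len(t) < 30:
        raise ValueError("need at least 30 dwells beyond the dead time")
    tau = float(np.mean(t) - t0)
    return DwellFitResults(
        model="single_exp",
        params=np.array([len(t), 1.0 / tau]),
        bse=np.array([np.nan, (1.0 / tau) / np.sqrt(len(t))]),
        tau_ms=(tau,),
        tau_err_ms=(tau / np.sqrt(len(t)),),
        n=len(t_all),
        bin_width_ms=np.nan,
        first_bin_excluded=False,
        method=f"mle_censored(t0={t0:g}ms)",
    )


def fit_dwell_single_exp(dwells_ms, bin_width_ms=4.0, exclude_first_bin=True, **kw) -> DwellFitResults:
    """Functional wrapper around :class:`SingleExponentialDwellModel`."""
    return SingleExponentialDwellModel(dwells_ms, bin_width_ms, exclude_first_bin, **kw).fit()


def fit_dwell_convolution(dwells_ms, bin_width_ms=2.0, exclude_first_bin=True, **kw) -> DwellFitResults:
    """Functional wrapper around :class:`ConvolvedExponentialDwellModel`."""
    return ConvolvedExponentialDwellModel(dwells_ms, bin_width_ms, exclude_first_bin, **kw).fit()
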