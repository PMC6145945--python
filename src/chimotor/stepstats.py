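"""Population statistics of detected steps and runs.

Step-size histograms are fitted with a superposition of Gaussians (by
default three: backward at ~-1.1 nm, forward at ~+1.1 nm and double
forward at ~+2.2 nm); event ratios come from the analytic areas of the
fitted components.  Per-trajectory velocity is the least-squares slope of
the on-axis trace, and run lengths follow a single-exponential decay whose
mean, divided by the 1.04 nm chitobiose length, is the processivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .scheme import CHITOBIOSE_NM, processivity as _processivity
from .trajectory import AlignedTrajectory


@dataclass
class MixtureResults:
    """Sum-of-Gaussians fit of the step-size histogram.

    ``components`` is a list of (peak_nm, sd_nm, area) sorted by peak;
    ``ratios`` are areas normalized to one.
    """

    components: list
    ratios: np.ndarray
    n_events: int
    bin_width_nm: float
    bse: np.ndarray
    fallback_used: bool = False

    @property
    def peaks_nm(self) -> np.ndarray:
        return np.array([c[0] for c in self.components])

    def summary(self) -> str:
        lines = [f"Step-size mixture ({len(self.components)} Gaussians, n={self.n_events})"]
        for (peak, sd, _), ratio in zip(self.components, self.ratios):
            lines.append(f"  peak {peak:+5.2f} nm  sd {sd:.2f} nm  ratio {100 * ratio:5.1f} %")
        return "\n".join(lines)

    def plot(self, sizes_nm=None, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xs = np.linspace(min(p for p, _, _ in self.components) - 1.5,
                         max(p for p, _, _ in self.components) + 1.5, 400)
        total = np.zeros_like(xs)
        for peak, sd, area in self.components:
            comp = area / (sd * np.sqrt(2 * np.pi)) * np.exp(-((xs - peak) ** 2) / (2 * sd**2))
            total += comp
            ax.plot(xs, comp * self.bin_width_nm, "--", lw=1)
        ax.plot(xs, total * self.bin_width_nm, "C0")
        if sizes_nm is not None:
            edges = np.arange(xs[0], xs[-1], self.bin_width_nm)
            ax.hist(sizes_nm, bins=edges, alpha=0.4)
        ax.set_xlabel("step size (nm)")
        ax.set_ylabel("counts")
        return ax


def _gauss_sum(x, *params):
    """params = (amp1, mu1, sd1, amp2, mu2, sd2, ...)"""
    y = np.zeros_like(x)
    for i in range(0, len(params), 3):
        a, mu, sd = params[i : i + 3]
        y = y + a * np.exp(-((x - mu) ** 2) / (2.0 * sd**2))
    return y


class StepSizeMixtureModel:
    """Least-squares Gaussian-mixture fit to the binned step sizes.

    Initialization places the forward component at the dominant positive
    mode, the double at twice it, the backward at its negative; when that
    fit fails to converge, a k-means pass over the sizes seeds a retry.
    """

    def __init__(self, sizes_nm, n_components: int = 3, bin_width_nm: float = 0.3) -> None:
        self.sizes = np.asarray(sizes_nm, dtype=float)
        if len(self.sizes) == 0:
            raise ValueError("no step sizes given")
        self.n_components = n_components
        self.bin_width_nm = bin_width_nm

    def _histogram(self):
        lo = np.floor(self.sizes.min() / self.bin_width_nm) * self.bin_width_nm - self.bin_width_nm
        hi = np.ceil(self.sizes.max() / self.bin_width_nm) * self.bin_width_nm + self.bin_width_nm
        edges = np.arange(lo, hi + self.bin_width_nm, self.bin_width_nm)
        counts, _ = np.histogram(self.sizes, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        return centers, counts.astype(float)

    def _default_init(self, centers, counts):
        pos = self.sizes[self.sizes > 0]
        mode = np.median(pos) if len(pos) else np.median(self.sizes)
        if self.n_components == 3:
            mus = [-mode, mode, 2.0 * mode]
        elif self.n_components == 2:
            mus = [-mode, mode]
        elif self.n_components == 1:
            mus = [np.median(self.sizes)]
        else:
            qs = np.linspace(0.05, 0.95, self.n_components)
            mus = list(np.quantile(self.sizes, qs))
        p0 = []
        for mu in mus:
            amp = max(counts[np.argmin(np.abs(centers - mu))], 1.0)
            p0 += [amp, mu, 0.3]
        return p0

    def _kmeans_init(self, centers, counts):
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=self.n_components, n_init=10, random_state=0).fit(
            self.sizes.reshape(-1, 1)
        )
        p0 = []
        for mu in sorted(km.cluster_centers_.ravel()):
            amp = max(counts[np.argmin(np.abs(centers - mu))], 1.0)
            p0 += [amp, float(mu), 0.3]
        return p0

    def fit(self) -> MixtureResults:
        centers, counts = self._histogram()
        lo = [0.0, -np.inf, 0.02] * self.n_components
        hi = [np.inf, np.inf, 5.0] * self.n_components
        fallback = False
        try:
            popt, pcov = curve_fit(
                _gauss_sum, centers, counts, p0=self._default_init(centers, counts),
                bounds=(lo, hi), maxfev=20000,
            )
        except RuntimeError:
            fallback = True
            popt, pcov = curve_fit(
                _gauss_sum, centers, counts, p0=self._kmeans_init(centers, counts),
                bounds=(lo, hi), maxfev=20000,
            )
        bse = np.sqrt(np.diag(pcov))
        comps = []
        for i in range(0, len(popt), 3):
            a, mu, sd = popt[i : i + 3]
            # analytic area in event counts: integral / bin width
            area = a * sd * np.sqrt(2.0 * np.pi) / self.bin_width_nm
            comps.append((float(mu), float(sd), float(area)))
        comps.sort(key=lambda c: c[0])
        areas = np.array([c[2] for c in comps])
        if np.any(areas <= 0) or areas.sum() <= 0:
            raise RuntimeError("mixture fit produced a non-positive component area")
        return MixtureResults(
            components=comps,
            ratios=areas / areas.sum(),
            n_events=len(self.sizes),
            bin_width_nm=self.bin_width_nm,
            bse=bse,
            fallback_used=fallback,
        )


def fit_step_mixture(sizes_nm, n_components: int = 3, bin_width_nm: float = 0.3) -> MixtureResults:
    """Functional wrapper around :class:`StepSizeMixtureModel`."""
    return StepSizeMixtureModel(sizes_nm, n_components, bin_width_nm).fit()


def fit_velocity(aligned: AlignedTrajectory) -> float:
    """Average velocity (nm/s): least-squares slope of on-axis vs time."""
    if len(aligned) < 10:
        raise ValueError("need at least 10 frames for a velocity fit")
    slope_nm_per_ms = np.polyfit(aligned.t_ms, aligned.on_axis, 1)[0]
    return float(slope_nm_per_ms * 1000.0)


@dataclass
class RunLengthResults:
    """Exponential fit of the run-length distribution."""

    mean_run_length_nm: float
    mean_err_nm: float
    processivity: int
    n: int
    bin_width_nm: float

    def summary(self) -> str:
        return (
            f"Run length: mean {self.mean_run_length_nm:.1f} +/- {self.mean_err_nm:.1f} nm "
            f"(n={self.n}) -> processivity {self.processivity} "
            f"({self.mean_run_length_nm:.1f} nm / {CHITOBIOSE_NM} nm)"
        )


def fit_run_length(run_lengths_nm, bin_width_nm: float = 10.0,
                   exclude_first_bin: bool = True) -> RunLengthResults:
    """Single-exponential fit to the binned run lengths.

    The first bin is excluded by the same convention as the dwell fits
    (short runs are depleted by the detection limit).  Mean run length is
    1/b; processivity is the mean divided by the chitobiose length,
    rounded to an integer.
    """
    r = np.asarray(run_lengths_nm, dtype=float)
    if len(r) < 20:
        raise ValueError("need at least 20 run lengths")
    upper = r.max() + bin_width_nm
    edges = np.arange(0.0, upper + bin_width_nm, bin_width_nm)
    counts, _ = np.histogram(r, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if exclude_first_bin:
        centers, counts = centers[1:], counts[1:].astype(float)
    b0 = 1.0 / max(np.mean(r), 1e-9)
    a0 = max(counts.max(), 1.0) * np.exp(b0 * centers[0])
    popt, pcov = curve_fit(
        lambda x, a, b: a * np.exp(-b * x), centers, counts, p0=[a0, b0],
        bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000,
    )
    mean = 1.0 / popt[1]
    err = np.sqrt(pcov[1, 1]) / popt[1] ** 2
    return RunLengthResults(
        mean_run_length_nm=float(mean),
        mean_err_nm=float(err),
        processivity=_processivity(mean),
        n=len(r),
        bin_width_nm=bin_width_nm,
    )


def fit_length_distribution(values, kind: str = "exponential", **kw):
    """Optional helper for other length distributions (e.g. fibril lengths).

    ``kind="lognormal"`` fits a log-normal by moments of log-values;
    ``kind="exponential"`` defers to :func:`fit_run_length`.
    """
    if kind == "exponential":
        return fit_run_length(values, **kw)
    if kind == "lognormal":
        v = np.asarray(values, dtype=float)
        if np.any(v <= 0):
            raise ValueError("log-normal fit requires positive values")
        logs = np.log(v)
        return {"mu": float(np.mean(logs)), "sigma": float(np.std(logs, ddof=1)),
                "median": float(np.exp(np.mean(logs))), "n": len(v)}
    raise ValueError("kind must be 'exponential' or 'lognormal'")
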