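"""Chi-square step detection with counter-fit model selection.

Implements the iterative plateau-splitting step finder of Kerssemakers
type for piecewise-constant traces in noise.  The fit with ``n`` steps is
grown greedily: at each round every current plateau is searched
exhaustively for the single split that removes the most residual variance,
and the best split over all plateaus is accepted.  Because the residual
chi-square always decreases with more steps, the step *count* is selected
with a counter-fit: a phase-shifted staircase with one step at the
midpoint of every plateau of the n-step fit.  The quality ratio

    S(n) = chi2(counter-fit) / chi2(fit)

peaks at the true step count — a correct fit leaves the counter-fit
maximally wrong, while over- or under-fitting drags both toward each
other.  Traces whose S never rises above a threshold show no clear step
structure and are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class StepFitResult:
    """Piecewise-constant fit with ``n_steps`` boundaries.

    Boundary convention: boundary ``b`` separates frames ``[start, b)``
    from ``[b, ...)`` (0-based, half-open), i.e. the step happens between
    frames ``b-1`` and ``b``.
    """

    boundaries: np.ndarray  # strictly increasing frame indices
    levels: np.ndarray      # plateau means, len == len(boundaries) + 1
    chi2: float             # residual sum of squares
    n_steps: int
    s_value: Optional[float] = None

    def predict(self, n_frames: int) -> np.ndarray:
        """Reconstruct the fitted staircase as a per-frame array."""
        edges = np.concatenate([[0], self.boundaries, [n_frames]])
        out = np.empty(n_frames)
        for lo, hi, lev in zip(edges[:-1], edges[1:], self.levels):
            out[lo:hi] = lev
        return out


@dataclass
class StepFindResults:
    """Outcome of :class:`StepFinder.fit`: nested fits plus S-value selection."""

    fits: list                      # StepFitResult for n = 1..max reached
    s_curve: list                   # (n_steps, S) pairs
    chosen_n: int
    accepted: bool
    s_threshold: float
    frame_interval_ms: float
    n_frames: int
    final: Optional[StepFitResult] = None  # S-chosen fit after pruning

    @property
    def best(self) -> StepFitResult:
        if self.final is not None:
            return self.final
        return self.fits[self.chosen_n - 1]

    def events(self) -> pd.DataFrame:
        """Step table of the chosen fit (see :func:`extract_events`)."""
        return extract_events(self.best, self.frame_interval_ms)

    def summary(self) -> str:
        lines = [
            "Step-finding summary",
            f"  frames:        {self.n_frames}",
            f"  chosen steps:  {self.chosen_n}",
            f"  max S-value:   {max(s for _, s in self.s_curve):.2f} "
            f"(threshold {self.s_threshold:g})",
            f"  accepted:      {self.accepted}",
            f"  residual chi2: {self.best.chi2:.3f} nm^2",
        ]
        return "\n".join(lines)

    def plot(self, t_ms=None, ax=None):
        """Overlay the fitted staircase on the trace times."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if t_ms is None:
            t_ms = np.arange(self.n_frames) * self.frame_interval_ms
        ax.plot(t_ms, self.best.predict(self.n_frames), drawstyle="steps-post")
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("on-axis position (nm)")
        return ax


def _segment_chi2(y2sum: float, ysum: float, n: int) -> float:
    return y2sum - ysum * ysum / n


def best_single_step(segment: np.ndarray, min_plateau: int = 3):
    """Exhaustive best split of one segment into two plateaus.

    Evaluates every admissible split index ``t`` (both sides at least
    ``min_plateau`` frames) and returns the one minimizing the total
    residual sum of squares of the two plateau means; ties break toward
    the earlier index.

    Returns
    -------
    (split, left_mean, right_mean, reduction)
        ``split`` is the local boundary index, or ``None`` with zero
        reduction when the segment is too short to split.
    """
    y = np.asarray(segment, dtype=float)
    n = len(y)
    if n < 2 * min_plateau:
        return None, np.nan, np.nan, 0.0
    S = np.concatenate([[0.0], np.cumsum(y)])
    Q = np.concatenate([[0.0], np.cumsum(y * y)])
    t = np.arange(min_plateau, n - min_plateau + 1)
    left = Q[t] - S[t] ** 2 / t
    right = (Q[n] - Q[t]) - (S[n] - S[t]) ** 2 / (n - t)
    chi2_split = left + right
    i = int(np.argmin(chi2_split))  # argmin takes the first (earliest) tie
    split = int(t[i])
    chi2_full = _segment_chi2(Q[n], S[n], n)
    reduction = chi2_full - chi2_split[i]
    return split, float(S[split] / split), float((S[n] - S[split]) / (n - split)), float(reduction)


def fit_step_tree(
    series: np.ndarray, max_steps: int, min_plateau: int = 3
) -> list:
    """Greedy nested step fits: one accepted split per round.

    Each round applies :func:`best_single_step` to every current plateau
    and accepts the single split with the largest chi-square reduction;
    the fit after every round is recorded.  Stops early when no plateau
    admits a split.  Only the freshly created plateaus are re-searched, so
    a full tree costs O(n log n) on typical staircases.
    """
    y = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("series must be finite")
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    n = len(y)

    # plateau record: (start, end, best_local_split, reduction)
    def search(start: int, end: int):
        split, _, _, red = best_single_step(y[start:end], min_plateau)
        return (start, end, None if split is None else start + split, red)

    plateaus = [search(0, n)]
    fits: list[StepFitResult] = []
    S = np.concatenate([[0.0], np.cumsum(y)])
    Q = np.concatenate([[0.0], np.cumsum(y * y)])

    for _ in range(max_steps):
        reductions = [p[3] for p in plateaus]
        k = int(np.argmax(reductions))
        start, end, split, red = plateaus[k]
        if split is None or red <= 0.0:
            break
        plateaus[k : k + 1] = [search(start, split), search(split, end)]
        edges = np.array([p[0] for p in plateaus] + [n])
        boundaries = edges[1:-1]
        counts = np.diff(edges)
        sums = S[edges[1:]] - S[edges[:-1]]
        levels = sums / counts
        chi2 = float(np.sum((Q[edges[1:]] - Q[edges[:-1]]) - sums**2 / counts))
        fits.append(
            StepFitResult(
                boundaries=boundaries.copy(),
                levels=levels,
                chi2=chi2,
                n_steps=len(boundaries),
            )
        )
    return fits


def _counter_fit_chi2_cached(n, S, Q, fit: StepFitResult) -> float:
    edges = np.concatenate([[0], fit.boundaries, [n]])
    lo, hi = edges[:-1], edges[1:]
    mids = ((lo + hi) // 2)[hi - lo >= 2]
    mids = mids[(mids > 0) & (mids < n)]
    cedges = np.unique(np.concatenate([[0], mids, [n]])).astype(int)
    counts = np.diff(cedges)
    sums = S[cedges[1:]] - S[cedges[:-1]]
    return float(np.sum((Q[cedges[1:]] - Q[cedges[:-1]]) - sums**2 / counts))


def counter_fit_chi2(series: np.ndarray, fit: StepFitResult) -> float:
    """Chi-square of the phase-shifted counter staircase for one fit.

    One counter-boundary is placed at the midpoint of every plateau of the
    fit (plateaus shorter than 2 frames contribute none); counter levels
    are the data means between counter-boundaries.
    """
    y = np.asarray(series, dtype=float)
    S = np.concatenate([[0.0], np.cumsum(y)])
    Q = np.concatenate([[0.0], np.cumsum(y * y)])
    return _counter_fit_chi2_cached(len(y), S, Q, fit)


def s_value_curve(series: np.ndarray, fits: Sequence[StepFitResult]):
    """S(n) = chi2(counter-fit)/chi2(fit) for each nested fit.

    Returns the list of (n_steps, S) pairs and the n maximizing S.  A
    perfect (noise-free) fit has chi2 = 0 and S = inf.
    """
    y = np.asarray(series, dtype=float)
    S_cum = np.concatenate([[0.0], np.cumsum(y)])
    Q_cum = np.concatenate([[0.0], np.cumsum(y * y)])
    s_curve = []
    for f in fits:
        cchi2 = _counter_fit_chi2_cached(len(y), S_cum, Q_cum, f)
        if f.chi2 <= 0.0:
            s = np.inf
        else:
            s = cchi2 / f.chi2
        f.s_value = s
        s_curve.append((f.n_steps, s))
    if not s_curve:
        return [], 0
    chosen = max(s_curve, key=lambda p: p[1])[0]
    return s_curve, chosen


def prune_small_steps(
    series: np.ndarray,
    fit: StepFitResult,
    min_step_nm: float,
    t_min: float = 0.0,
) -> StepFitResult:
    """Merge plateaus across sub-threshold or insignificant steps.

    The greedy chi-square fit, driven to the S-optimal step count, still
    places occasional boundaries inside long pauses where filtered noise
    mimics a small step.  A boundary is removed when its level difference
    is below ``min_step_nm`` or (if ``t_min`` > 0) when the difference is
    below ``t_min`` local standard errors — the SE combining the residual
    scatter of the two flanking plateaus.  Boundaries are merged weakest
    first, plateau means and chi2 being recomputed after each merge.
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    S = np.concatenate([[0.0], np.cumsum(y)])
    Q = np.concatenate([[0.0], np.cumsum(y * y)])
    edges = list(np.concatenate([[0], fit.boundaries, [n]]).astype(int))

    def levels_of(e):
        e = np.asarray(e)
        return (S[e[1:]] - S[e[:-1]]) / np.diff(e)

    def step_score(e, levels, k):
        """(|step|, t-statistic) of boundary k of edge list e."""
        lo, b, hi = e[k], e[k + 1], e[k + 2]
        nl, nr = b - lo, hi - b
        delta = levels[k + 1] - levels[k]
        rssl = Q[b] - Q[lo] - (S[b] - S[lo]) ** 2 / nl
        rssr = Q[hi] - Q[b] - (S[hi] - S[b]) ** 2 / nr
        dof = max(nl + nr - 2, 1)
        sd = np.sqrt(max(rssl + rssr, 0.0) / dof)
        se = sd * np.sqrt(1.0 / nl + 1.0 / nr)
        t = np.inf if se == 0 else abs(delta) / se
        return abs(delta), t

    levels = levels_of(edges)
    while len(edges) > 2:
        scores = [step_score(edges, levels, k) for k in range(len(edges) - 2)]
        weak = [
            k for k, (d, t) in enumerate(scores)
            if d < min_step_nm or (t_min > 0 and t < t_min)
        ]
        if not weak:
            break
        k = min(weak, key=lambda k: scores[k][1])
        del edges[k + 1]
        levels = levels_of(edges)
    e = np.asarray(edges)
    counts = np.diff(e)
    sums = S[e[1:]] - S[e[:-1]]
    chi2 = float(np.sum((Q[e[1:]] - Q[e[:-1]]) - sums**2 / counts))
    return StepFitResult(
        boundaries=e[1:-1].copy(), levels=sums / counts, chi2=chi2, n_steps=len(e) - 2,
        s_value=fit.s_value,
    )


def refine_boundaries(
    series: np.ndarray, fit: StepFitResult, window: int = 6, passes: int = 2
) -> StepFitResult:
    """Re-optimize each boundary locally against an unfiltered trace.

    Median filtering broadens step edges by up to its half-window, which
    biases plateau durations long; this pass slides every boundary within
    ``+/-window`` frames (neighbours held fixed) to the position that
    minimizes the residual chi-square on the given (raw) series, then
    recomputes plateau means.  Two passes are enough in practice.
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    S = np.concatenate([[0.0], np.cumsum(y)])
    Q = np.concatenate([[0.0], np.cumsum(y * y)])
    bounds = list(map(int, fit.boundaries))
    if not bounds:
        return fit

    def chi2_pair(lo, b, hi):
        nl, nr = b - lo, hi - b
        sl, sr = S[b] - S[lo], S[hi] - S[b]
        return (Q[b] - Q[lo] - sl * sl / nl) + (Q[hi] - Q[b] - sr * sr / nr)

    for _ in range(passes):
        moved = False
        for i, b in enumerate(bounds):
            lo = bounds[i - 1] if i > 0 else 0
            hi = bounds[i + 1] if i + 1 < len(bounds) else n
            cand = np.arange(max(lo + 1, b - window), min(hi - 1, b + window) + 1)
            if len(cand) == 0:
                continue
            costs = [chi2_pair(lo, c, hi) for c in cand]
            best = int(cand[int(np.argmin(costs))])
            if best != b:
                bounds[i] = best
                moved = True
        if not moved:
            break
    e = np.concatenate([[0], bounds, [n]]).astype(int)
    counts = np.diff(e)
    sums = S[e[1:]] - S[e[:-1]]
    chi2 = float(np.sum((Q[e[1:]] - Q[e[:-1]]) - sums**2 / counts))
    return StepFitResult(
        boundaries=np.array(bounds, dtype=int), levels=sums / counts, chi2=chi2,
        n_steps=len(bounds), s_value=fit.s_value,
    )


def extract_events(fit: StepFitResult, frame_interval_ms: float) -> pd.DataFrame:
    """Step table from an accepted fit.

    One row per boundary: step size (level difference across the
    boundary, nm) and the dwell spent on the preceding plateau (ms).  The
    dwell of the first step is left-censored — the start of its plateau
    is the start of observation, not a detected step — and is flagged by
    ``dwell_censored`` so that downstream dwell fits can drop it.
    """
    rows = []
    edges = np.concatenate([[0], fit.boundaries])
    for i, b in enumerate(fit.boundaries):
        rows.append(
            {
                "boundary_frame": int(b),
                "t_ms": b * frame_interval_ms,
                "size_nm": fit.levels[i + 1] - fit.levels[i],
                "dwell_ms": (b - edges[i]) * frame_interval_ms,
                "dwell_censored": i == 0,
            }
        )
    return pd.DataFrame(
        rows, columns=["boundary_frame", "t_ms", "size_nm", "dwell_ms", "dwell_censored"]
    )


class StepFinder:
    """Model object tying the pieces together for one trace.

    Parameters
    ----------
    series : array
        Median-filtered on-axis positions (nm), one per frame.
    frame_interval_ms : float
    min_plateau : int
        Minimum plateau length in frames (default 3, i.e. 1.5 ms at
        0.5 ms sampling); prevents single-frame plateaus.
    s_threshold : float
        Minimum peak S-value for the trace to count as showing clear
        step structure.
    prune_min_step_nm : float or None
        After S-selection, steps smaller than this are merged away
        (default 0.55 nm, half the unit step); ``None`` disables pruning.
    prune_t_min : float
        Minimum local t-statistic of a step (level difference over its
        standard error); steps below it are merged.  0 disables.
    refine_series : array, optional
        Unfiltered trace on which boundaries are locally re-optimized
        after selection (undoes median-filter edge broadening).
    """

    def __init__(
        self,
        series,
        frame_interval_ms: float = 0.5,
        min_plateau: int = 3,
        s_threshold: float = 2.0,
        prune_min_step_nm: float | None = 0.55,
        prune_t_min: float = 5.0,
        refine_series=None,
    ) -> None:
        self.series = np.asarray(series, dtype=float)
        self.frame_interval_ms = frame_interval_ms
        self.min_plateau = min_plateau
        self.s_threshold = s_threshold
        self.prune_min_step_nm = prune_min_step_nm
        self.prune_t_min = prune_t_min
        self.refine_series = None if refine_series is None else np.asarray(refine_series, float)

    def fit(self, max_steps: Optional[int] = None) -> StepFindResults:
        n = len(self.series)
        if max_steps is None:
            max_steps = max(1, n // (2 * self.min_plateau))
        fits = fit_step_tree(self.series, max_steps, self.min_plateau)
        if not fits:
            return StepFindResults(
                fits=[],
                s_curve=[],
                chosen_n=0,
                accepted=False,
                s_threshold=self.s_threshold,
                frame_interval_ms=self.frame_interval_ms,
                n_frames=n,
            )
        s_curve, chosen = s_value_curve(self.series, fits)
        smax = max(s for _, s in s_curve)
        final = fits[chosen - 1]
        if self.prune_min_step_nm is not None:
            final = prune_small_steps(self.series, final, self.prune_min_step_nm, self.prune_t_min)
        if self.refine_series is not None and len(self.refine_series) == n:
            final = refine_boundaries(self.refine_series, final)
            if self.prune_min_step_nm is not None:
                final = prune_small_steps(
                    self.refine_series, final, self.prune_min_step_nm, self.prune_t_min
                )
        return StepFindResults(
            fits=fits,
            s_curve=s_curve,
            chosen_n=chosen,
            accepted=bool(smax >= self.s_threshold),
            s_threshold=self.s_threshold,
            frame_interval_ms=self.frame_interval_ms,
            n_frames=n,
            final=final,
        )
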