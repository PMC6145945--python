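"""Trajectory containers, axis rotation and median denoising.

A raw trajectory is a uniformly sampled 2D track of a scattering probe
(time in ms, positions in nm).  Before step detection the track is rotated
so that one axis (the *on-axis*) lies along the direction of motion, which
for a processive chitinase follows the long axis of the chitin fibril.  The
rotation used is

    on_axis  =  cos(theta) * x_raw + sin(theta) * y_raw
    off_axis = -sin(theta) * x_raw + cos(theta) * y_raw

where ``theta`` is the angle between the motion axis and the raw x-axis.
High-frequency localization noise is then reduced with a running median
over a short, symmetric time window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class NoClearAxisError(ValueError):
    """Raised when the position scatter has no dominant direction."""


@dataclass
class RawTrajectory:
    """Uniformly sampled 2D positions of one particle.

    Attributes
    ----------
    t_ms : ndarray
        Time stamps in milliseconds, strictly increasing on a uniform grid.
    x_nm, y_nm : ndarray
        Raw positions in nanometres.
    meta : dict
        Free-form metadata (seed, config echo, ground truth, ...).
    """

    t_ms: np.ndarray
    x_nm: np.ndarray
    y_nm: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x_nm = np.asarray(self.x_nm, dtype=float)
        self.y_nm = np.asarray(self.y_nm, dtype=float)
        if not (len(self.t_ms) == len(self.x_nm) == len(self.y_nm)):
            raise ValueError("t, x and y must have equal length")
        if len(self.t_ms) > 1:
            dt = np.diff(self.t_ms)
            if np.any(dt <= 0):
                raise ValueError("time stamps must be strictly increasing")
            if np.any(np.abs(dt - dt[0]) > 1e-9):
                idx = int(np.argmax(np.abs(dt - dt[0]) > 1e-9))
                raise ValueError(
                    f"non-uniform time grid at row {idx + 1} "
                    f"(dt={dt[idx]:g} ms, expected {dt[0]:g} ms)"
                )

    def __len__(self) -> int:
        return len(self.t_ms)

    @property
    def frame_interval_ms(self) -> float:
        if len(self.t_ms) < 2:
            raise ValueError("need at least two frames for a frame interval")
        return float(self.t_ms[1] - self.t_ms[0])

    @property
    def frames(self) -> np.ndarray:
        return np.arange(len(self.t_ms), dtype=int)


@dataclass
class AlignedTrajectory:
    """Trajectory rotated onto the motion axis.

    ``on_axis`` carries the stepping signal, ``off_axis`` should be noise
    around a constant.  ``filtered_on`` is the median-filtered on-axis
    trace used for step detection (``None`` until a filter is applied).
    """

    t_ms: np.ndarray
    on_axis: np.ndarray
    off_axis: np.ndarray
    theta: float
    filtered_on: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.t_ms)

    @property
    def frame_interval_ms(self) -> float:
        return float(self.t_ms[1] - self.t_ms[0])


def estimate_axis_angle(raw: RawTrajectory, min_eigenvalue_ratio: float = 2.0) -> float:
    """Estimate the motion-axis angle from the position covariance.

    The axis is the principal component of the (x, y) scatter; its sign is
    chosen so that the net displacement projects positively onto the
    on-axis.  For a processive motor the travelled distance dominates the
    localization noise, making the principal axis a robust estimate of the
    fibril direction.

    Parameters
    ----------
    raw : RawTrajectory
    min_eigenvalue_ratio : float
        Minimum ratio of the leading to trailing covariance eigenvalue.
        Below it the scatter is considered isotropic (a stuck particle)
        and :class:`NoClearAxisError` is raised.

    Returns
    -------
    float
        Angle theta in radians in (-pi, pi].
    """
    xy = np.column_stack([raw.x_nm, raw.y_nm])
    if len(xy) < 3:
        raise ValueError("need at least 3 points to estimate an axis")
    cov = np.cov(xy, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)  # ascending order
    if evals[0] <= 0:
        ratio = np.inf
    else:
        ratio = evals[1] / evals[0]
    if ratio < min_eigenvalue_ratio:
        raise NoClearAxisError(
            f"no clear motion axis: eigenvalue ratio {ratio:.2f} < {min_eigenvalue_ratio:g}"
        )
    v = evecs[:, 1]
    net = xy[-1] - xy[0]
    if np.dot(net, v) < 0:
        v = -v
    return float(np.arctan2(v[1], v[0]))


def rotate_to_axes(raw: RawTrajectory, theta: float) -> AlignedTrajectory:
    """Rotate a raw trajectory by ``theta`` onto on/off axes.

    Applies the rotation pair exactly as defined in the module docstring;
    the transform is an isometry, so pairwise distances are preserved.
    """
    x, y = raw.x_nm, raw.y_nm
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("positions must be finite")
    c, s = np.cos(theta), np.sin(theta)
    on = c * x + s * y
    off = -s * x + c * y
    return AlignedTrajectory(
        t_ms=raw.t_ms.copy(),
        on_axis=on,
        off_axis=off,
        theta=float(theta),
        meta=dict(raw.meta),
    )


def median_filter(
    series: np.ndarray, half_window_ms: float = 2.0, frame_interval_ms: float = 0.5
) -> np.ndarray:
    """Running median over a symmetric time window current +/- half_window.

    Samples within ``half_window_ms`` of each point are pooled (so the
    default +/-2 ms at 0.5 ms sampling spans 9 samples).  At the edges the
    window is truncated, not reflected: the first and last samples are
    medians of shorter, one-sided windows.
    """
    y = np.asarray(series, dtype=float)
    if frame_interval_ms <= 0:
        raise ValueError("frame_interval_ms must be positive")
    if half_window_ms < frame_interval_ms:
        raise ValueError("half window must be at least one frame interval")
    h = int(np.floor(half_window_ms / frame_interval_ms + 1e-9))
    n = len(y)
    if n == 0:
        return y.copy()
    out = np.empty(n)
    w = 2 * h + 1
    if n >= w:
        # interior: vectorized via a strided sliding window
        windows = np.lib.stride_tricks.sliding_window_view(y, w)
        out[h : n - h] = np.median(windows, axis=1)
        edge = h
    else:
        edge = n
    for i in range(min(edge, n)):
        out[i] = np.median(y[max(0, i - h) : i + h + 1])
    for i in range(max(n - edge, 0), n):
        out[i] = np.median(y[max(0, i - h) : i + h + 1])
    return out


def prepare_trajectory(
    raw: RawTrajectory,
    theta: Optional[float] = None,
    half_window_ms: float = 2.0,
    min_eigenvalue_ratio: float = 2.0,
) -> AlignedTrajectory:
    """Rotate onto the motion axis and median-filter the on-axis trace.

    ``theta`` overrides the PCA estimate (useful when the fibril direction
    is known from the image).
    """
    if theta is None:
        theta = estimate_axis_angle(raw, min_eigenvalue_ratio=min_eigenvalue_ratio)
    aligned = rotate_to_axes(raw, theta)
    aligned.filtered_on = median_filter(
        aligned.on_axis, half_window_ms=half_window_ms, frame_interval_ms=raw.frame_interval_ms
    )
    aligned.meta["median_half_window_ms"] = half_window_ms
    return aligned
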