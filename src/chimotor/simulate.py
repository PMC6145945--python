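"""Kinetic Monte Carlo simulator of processive-chitinase stepping.

The enzyme advances along a single chitin chain in ~1.1 nm increments (the
2.2 nm chitobiose repeat projected on the motion axis appears as 1.1 nm
because product release happens once per two sugar units; operationally we
simply use the measured step sizes).  Each cycle the simulator draws the
next event kind — 1-nm forward, 2-nm forward or backward — from fixed
probabilities, and a recovery (forward) step always follows a backward
step.  Dwell times are exponential, ``dt = ln(1/r)/k``; the pause before a
1-nm forward step is by default the *sum* of two exponential draws (fast
substrate-assisted catalysis, then slow product release +
decrystallization + chain sliding), which is what produces the observed
rise-and-decay dwell histogram.

Camera rendering samples the ideal staircase on a regular frame grid and
adds zero-mean Gaussian localization noise whose SD is redrawn at every
pause from a truncated Gaussian, emulating pause-to-pause variation of the
experimental localization precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .trajectory import RawTrajectory

EVENT_KINDS = ("forward1", "forward2", "backward", "recovery")

#: default time constants (ms) of the processive reaction cycle
DEFAULT_DWELL_TAUS_MS = {
    "forward1": (2.9, 23.9),  # catalysis, then release + decrystallization + sliding
    "forward2": (26.0,),
    "backward": (18.3,),
    "recovery": (17.1,),
}

#: default step-kind probabilities estimated from the step-size mixture areas
DEFAULT_STEP_RATIOS = {"forward": 0.693, "double": 0.142, "backward": 0.165}

DEFAULT_STEP_SIZES_NM = {"forward": 1.1, "double": 2.2, "backward": -1.1}


@dataclass
class SimConfig:
    """Configuration of the stepping simulator.

    Parameters
    ----------
    step_sizes : dict
        Displacements in nm for "forward", "double" and "backward" kinds.
        The recovery step reuses the forward size (it undoes a backward).
    step_ratios : dict
        Probabilities of choosing forward / double / backward; must sum
        to 1.  Recovery is not drawn — it always follows backward.
    dwell_taus_ms : dict
        Per-kind time constants in ms.  A 1-tuple means a single
        exponential; a 2-tuple means the dwell is the sum of two
        exponential draws (convolution of the two densities).
    frame_interval_ms : float
        Camera exposure spacing (default 0.5 ms).
    precision_peak_nm, precision_spread_nm, precision_floor_nm : float
        Pause-wise localization-noise SD is drawn from a Gaussian
        (peak, spread) truncated below at the floor.
    n_events, duration_ms : int / float
        Stop after this many events or this much simulated time
        (whichever is configured; n_events takes precedence).
    min_dwell_ms : float, optional
        If set, dwells are redrawn until they exceed this floor.  Used to
        build camera-resolvable fixtures for detector validation; leave
        ``None`` for physically faithful statistics.
    axis_angle_rad : float
        Orientation of the motion axis in the raw frame when rendering.
    rng_seed : int, optional
        Seed of the single generator used for the whole simulation.
    """

    step_sizes: dict = field(default_factory=lambda: dict(DEFAULT_STEP_SIZES_NM))
    step_ratios: dict = field(default_factory=lambda: dict(DEFAULT_STEP_RATIOS))
    dwell_taus_ms: dict = field(default_factory=lambda: dict(DEFAULT_DWELL_TAUS_MS))
    frame_interval_ms: float = 0.5
    precision_peak_nm: float = 0.34
    precision_spread_nm: float = 0.10
    precision_floor_nm: float = 0.05
    n_events: Optional[int] = None
    duration_ms: Optional[float] = None
    min_dwell_ms: Optional[float] = None
    tail_ms: float = 20.0
    axis_angle_rad: float = 0.0
    rng_seed: Optional[int] = None

    def validate(self) -> None:
        ratios = [self.step_ratios[k] for k in ("forward", "double", "backward")]
        if any(r < 0 or r > 1 for r in ratios):
            raise ValueError("step ratios must lie in [0, 1]")
        if abs(sum(ratios) - 1.0) > 1e-9:
            raise ValueError(f"step ratios must sum to 1 (got {sum(ratios)!r})")
        for kind, taus in self.dwell_taus_ms.items():
            if len(taus) not in (1, 2) or any(t <= 0 for t in taus):
                raise ValueError(f"dwell taus for {kind!r} must be 1 or 2 positive values")
        if self.frame_interval_ms <= 0:
            raise ValueError("frame_interval_ms must be positive")
        if self.precision_peak_nm <= 0:
            raise ValueError("precision_peak_nm must be positive")
        if self.n_events is None and self.duration_ms is None:
            raise ValueError("configure either n_events or duration_ms")
        if self.n_events is not None and self.n_events < 0:
            raise ValueError("n_events must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimEvent:
    """One stepping event: its kind, preceding dwell and displacement."""

    kind: str
    dwell_ms: float
    displacement_nm: float
    true_time_ms: float  # time at which the step occurs


@dataclass
class IdealTrajectory:
    """Noise-free piecewise-constant staircase.

    ``breakpoints_ms`` are the step times (strictly increasing) and
    ``levels_nm`` the plateau positions; ``len(levels) == len(breakpoints) + 1``.
    """

    breakpoints_ms: np.ndarray
    levels_nm: np.ndarray
    events: list

    def position_at(self, t_ms: np.ndarray) -> np.ndarray:
        """Level occupied at each query time (steps occur *at* breakpoints)."""
        idx = np.searchsorted(self.breakpoints_ms, np.asarray(t_ms, dtype=float), side="right")
        return self.levels_nm[idx]

    @property
    def duration_ms(self) -> float:
        return float(self.breakpoints_ms[-1]) if len(self.breakpoints_ms) else 0.0


def sample_dwell(k: float, r: float) -> float:
    """Inverse-CDF exponential dwell draw, ``ln(1/r)/k`` in seconds.

    ``k`` is the rate constant in s^-1 and ``r`` a uniform variate in
    (0, 1].  r = 1 maps to a zero dwell; r -> 0 to arbitrarily long ones.
    """
    if k <= 0:
        raise ValueError("rate constant must be positive")
    if not (0.0 < r <= 1.0):
        raise ValueError("r must lie in (0, 1]")
    return math.log(1.0 / r) / k


def _draw_dwell_ms(taus_ms, rng: np.random.Generator, floor_ms: Optional[float]) -> float:
    """Dwell in ms: one exponential draw per configured time constant, summed."""
    while True:
        dwell = 0.0
        for tau in taus_ms:
            k_per_s = 1000.0 / tau
            r = 1.0 - rng.random()  # uniform in (0, 1]
            dwell += sample_dwell(k_per_s, r) * 1000.0
        if floor_ms is None or dwell >= floor_ms:
            return dwell


def simulate_step_sequence(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> IdealTrajectory:
    """Draw the event sequence and build the ideal staircase.

    Each iteration picks forward / double / backward with the configured
    probabilities and a dwell from that kind's dwell model; a backward
    step is always followed immediately by a recovery step with its own
    dwell.  The staircase starts at level 0 at time 0.
    """
    cfg.validate()
    if rng is None:
        rng = cfg.rng()
    probs = np.array([cfg.step_ratios["forward"], cfg.step_ratios["double"], cfg.step_ratios["backward"]])
    sizes = cfg.step_sizes
    events: list[SimEvent] = []
    t = 0.0
    level = 0.0
    levels = [0.0]
    breakpoints: list[float] = []

    def done() -> bool:
        if cfg.n_events is not None:
            return len(events) >= cfg.n_events
        return t >= cfg.duration_ms

    pending_recovery = False
    while not done():
        if pending_recovery:
            kind, disp = "recovery", -sizes["backward"]
            pending_recovery = False
        else:
            choice = rng.choice(3, p=probs)
            if choice == 0:
                kind, disp = "forward1", sizes["forward"]
            elif choice == 1:
                kind, disp = "forward2", sizes["double"]
            else:
                kind, disp = "backward", sizes["backward"]
                pending_recovery = True
        dwell = _draw_dwell_ms(cfg.dwell_taus_ms[kind], rng, cfg.min_dwell_ms)
        t += dwell
        level += disp
        events.append(SimEvent(kind=kind, dwell_ms=dwell, displacement_nm=disp, true_time_ms=t))
        breakpoints.append(t)
        levels.append(level)

    return IdealTrajectory(
        breakpoints_ms=np.array(breakpoints, dtype=float),
        levels_nm=np.array(levels, dtype=float),
        events=events,
    )


def _draw_pause_sd(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Per-pause noise SDs from a positive-truncated Gaussian."""
    sds = np.empty(n)
    for i in range(n):
        while True:
            sd = rng.normal(cfg.precision_peak_nm, cfg.precision_spread_nm)
            if sd >= cfg.precision_floor_nm:
                sds[i] = sd
                break
    return sds


def render_noisy_trajectory(
    ideal: IdealTrajectory, cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> RawTrajectory:
    """Sample the staircase on the camera grid and add pause-wise noise.

    The on-axis coordinate follows the staircase; the off-axis coordinate
    is pure noise around zero.  One noise SD is drawn per pause (for each
    axis independently), then the pair (on, off) is rotated into the raw
    frame by the configured axis angle.
    """
    cfg.validate()
    if rng is None:
        rng = cfg.rng()
    total_ms = ideal.duration_ms + cfg.tail_ms
    n_frames = int(np.floor(total_ms / cfg.frame_interval_ms)) + 1
    if len(ideal.levels_nm) == 0 or n_frames <= 0:
        return RawTrajectory(t_ms=np.array([]), x_nm=np.array([]), y_nm=np.array([]))
    t = np.arange(n_frames) * cfg.frame_interval_ms
    on = ideal.position_at(t)
    pause_idx = np.searchsorted(ideal.breakpoints_ms, t, side="right")
    n_pauses = len(ideal.levels_nm)
    sd_on = _draw_pause_sd(cfg, rng, n_pauses)
    sd_off = _draw_pause_sd(cfg, rng, n_pauses)
    noise_on = rng.normal(0.0, 1.0, n_frames) * sd_on[pause_idx]
    noise_off = rng.normal(0.0, 1.0, n_frames) * sd_off[pause_idx]
    on_noisy = on + noise_on
    off_noisy = noise_off
    # inverse of the on/off rotation: x = cos*on - sin*off, y = sin*on + cos*off
    c, s = np.cos(cfg.axis_angle_rad), np.sin(cfg.axis_angle_rad)
    x = c * on_noisy - s * off_noisy
    y = s * on_noisy + c * off_noisy
    meta = {
        "config": cfg.to_dict(),
        "seed": cfg.rng_seed,
        "true_breakpoints_ms": ideal.breakpoints_ms.tolist(),
        "true_levels_nm": ideal.levels_nm.tolist(),
        "true_events": [asdict(e) for e in ideal.events],
        "pause_sd_on_nm": sd_on.tolist(),
    }
    return RawTrajectory(t_ms=t, x_nm=x, y_nm=y, meta=meta)


def simulate_trajectory(cfg: SimConfig) -> RawTrajectory:
    """Convenience: event sequence + camera rendering with one generator."""
    rng = cfg.rng()
    ideal = simulate_step_sequence(cfg, rng)
    return render_noisy_trajectory(ideal, cfg, rng)


def synth_spot_stack(
    track: RawTrajectory,
    psf_sigma_nm: float = 130.0,
    photons: float = 5.0e4,
    pixel_nm: float = 66.7,
    shape: tuple = (24, 24),
    background: float = 40.0,
    shot_noise: bool = True,
    rng_seed: Optional[int] = None,
) -> np.ndarray:
    """Render a diffraction-limited spot stack for a track (12-bit camera).

    Synthetic fixture for the localization module: each frame contains one
    symmetric 2D-Gaussian spot of integrated intensity ``photons`` at the
    track position (track (0,0) maps to the field centre), on a constant
    background, with optional Poisson counting noise, saturated at 4095.

    Returns a ``(n_frames, ny, nx)`` uint16 array.
    """
    if psf_sigma_nm <= 0 or photons < 0 or pixel_nm <= 0:
        raise ValueError("psf_sigma_nm, photons and pixel_nm must be positive")
    ny, nx = shape
    cx = (nx - 1) / 2.0 * pixel_nm
    cy = (ny - 1) / 2.0 * pixel_nm
    xs = track.x_nm + cx
    ys = track.y_nm + cy
    margin = 2 * psf_sigma_nm
    if np.any(xs < margin) or np.any(xs > (nx - 1) * pixel_nm - margin) or np.any(
        ys < margin
    ) or np.any(ys > (ny - 1) * pixel_nm - margin):
        raise ValueError("track leaves the synthetic field of view")
    rng = np.random.default_rng(rng_seed)
    # pixel-integrated Gaussian via erf differences (exact spot model)
    from scipy.special import erf

    edges_x = (np.arange(nx + 1) - 0.5) * pixel_nm
    edges_y = (np.arange(ny + 1) - 0.5) * pixel_nm
    s2 = psf_sigma_nm * math.sqrt(2.0)
    frames = np.empty((len(track), ny, nx), dtype=np.uint16)
    for i in range(len(track)):
        fx = 0.5 * (erf((edges_x[1:] - xs[i]) / s2) - erf((edges_x[:-1] - xs[i]) / s2))
        fy = 0.5 * (erf((edges_y[1:] - ys[i]) / s2) - erf((edges_y[:-1] - ys[i]) / s2))
        img = photons * np.outer(fy, fx) + background
        if shot_noise:
            img = rng.poisson(img).astype(float)
        frames[i] = np.clip(np.round(img), 0, 4095).astype(np.uint16)
    return frames


def synth_kinetics_dataset(
    kcat_per_s: float,
    km_uM: float,
    ksi_uM: float,
    concentrations_uM,
    noise_cv: float = 0.0,
    rng_seed: Optional[int] = None,
):
    """Turnover-vs-[S] table from Michaelis-Menten kinetics with substrate inhibition.

    v([S]) = kcat [S] / (Km + [S] + [S]^2 / Ksi), with multiplicative
    Gaussian noise of coefficient of variation ``noise_cv``.  Returns a
    pandas DataFrame with columns conc_uM, rate_per_s.
    """
    import pandas as pd

    if kcat_per_s <= 0 or km_uM <= 0 or ksi_uM <= 0:
        raise ValueError("kcat, Km and Ksi must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    s = np.asarray(concentrations_uM, dtype=float)
    v = kcat_per_s * s / (km_uM + s + s**2 / ksi_uM)
    if noise_cv > 0:
        rng = np.random.default_rng(rng_seed)
        v = v * (1.0 + noise_cv * rng.standard_normal(len(s)))
    return pd.DataFrame({"conc_uM": s, "rate_per_s": v})
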