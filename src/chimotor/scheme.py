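"""Chemo-mechanical kinetic scheme of the processive cycle.

The fitted dwell-time constants assemble into a reaction cycle: from the
forward-stepped state (Michaelis complex, state A) fast substrate-assisted
catalysis (tau_cat ~ 3 ms) competes with a backward step (tau_back ~ 18 ms).
After catalysis the product is released (tau_release), one chitobiose unit
is decrystallized and the chain slides forward (tau_dec, measured directly
as the recovery-step dwell since recovery repeats the mechanics without
product release).  The long component of the forward dwell lumps release +
decrystallization + sliding, so

    tau_release = tau_forward_long - tau_dec.

Because the track behind the motor is consumed by catalysis (burnt
bridge), the forward/backward Brownian excursions are rectified forward
with probability k_cat / (k_cat + k_back).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

#: gas constant in kcal mol^-1 K^-1
R_KCAL = 1.987e-3
#: length of the reaction product chitobiose (nm); the motor's unit step
CHITOBIOSE_NM = 1.04
#: 25 degrees C
T_STANDARD_K = 298.15


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass
class KineticScheme:
    """Time constants (ms) of the processive reaction cycle.

    ``tau_forward_long`` lumps product release + decrystallization +
    chain sliding; ``tau_dec`` (decrystallization + sliding) comes from
    the recovery-step dwell; their difference is the product-release time
    constant.  Rates are reciprocals in s^-1, reported at 3 significant
    figures (`k_*`) with exact values available (`k_*_exact`).
    """

    tau_cat_ms: float
    tau_forward_long_ms: float
    tau_dec_ms: float
    tau_back_ms: float
    tau_forward2_ms: Optional[float] = None
    d_step_nm: float = CHITOBIOSE_NM

    def __post_init__(self) -> None:
        for name in ("tau_cat_ms", "tau_forward_long_ms", "tau_dec_ms", "tau_back_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    # --- time constants -------------------------------------------------
    @property
    def tau_release_ms(self) -> float:
        return self.tau_forward_long_ms - self.tau_dec_ms

    @property
    def release_physical(self) -> bool:
        """False when tau_forward_long <= tau_dec (non-physical release time)."""
        return self.tau_release_ms > 0

    # --- rates (s^-1) ---------------------------------------------------
    @property
    def k_cat_exact(self) -> float:
        return 1000.0 / self.tau_cat_ms

    @property
    def k_back_exact(self) -> float:
        return 1000.0 / self.tau_back_ms

    @property
    def k_dec_exact(self) -> float:
        return 1000.0 / self.tau_dec_ms

    @property
    def k_release_exact(self) -> float:
        if not self.release_physical:
            raise ValueError("release time constant is non-physical (forward_long <= dec)")
        return 1000.0 / self.tau_release_ms

    @property
    def k_cat(self) -> float:
        return _round_sig(self.k_cat_exact)

    @property
    def k_back(self) -> float:
        return _round_sig(self.k_back_exact)

    @property
    def k_dec(self) -> float:
        return _round_sig(self.k_dec_exact)

    @property
    def k_release(self) -> float:
        return _round_sig(self.k_release_exact)

    @classmethod
    def from_dwell_fits(cls, forward1, backward, recovery, forward2=None, d_step_nm=CHITOBIOSE_NM):
        """Assemble the scheme from category-wise :class:`DwellFitResults`."""
        return cls(
            tau_cat_ms=forward1.tau_short_ms,
            tau_forward_long_ms=forward1.tau_long_ms,
            tau_dec_ms=recovery.tau_ms[0],
            tau_back_ms=backward.tau_ms[0],
            tau_forward2_ms=None if forward2 is None else forward2.tau_ms[0],
            d_step_nm=d_step_nm,
        )

    def summary(self) -> str:
        lines = [
            "Processive reaction cycle (time constants in ms, rates in s^-1)",
            f"  substrate-assisted catalysis: tau = {self.tau_cat_ms:5.1f}  (k_cat = {self.k_cat:g})",
            f"  release+decrystallization+sliding: tau = {self.tau_forward_long_ms:5.1f}",
            f"  decrystallization+sliding:    tau = {self.tau_dec_ms:5.1f}  (k_dec = {self.k_dec:g})",
            f"  product release (derived):    tau = {self.tau_release_ms:5.1f}",
            f"  backward step:                tau = {self.tau_back_ms:5.1f}  (k_back = {self.k_back:g})",
        ]
        if self.tau_forward2_ms is not None:
            lines.append(f"  2-nm forward step:            tau = {self.tau_forward2_ms:5.1f}")
        lines.append(f"  unit step d = {self.d_step_nm:g} nm")
        lines.append(f"  P(catalysis from state A) = {catalysis_probability(self):.1f} %")
        return "\n".join(lines)


@dataclass
class ThermoResult:
    """Equilibrium between forward- and backward-stepped states."""

    K_eq_raw: float          # k_dec / k_back as computed
    K_eq: float              # rounded to 1 decimal (reporting convention)
    delta_G_kcal_mol: float  # from the raw ratio
    T_kelvin: float
    R_kcal: float = R_KCAL


def catalysis_probability(scheme: KineticScheme) -> float:
    """Probability (%) that catalysis wins over the backward step in state A.

    100 * k_cat / (k_cat + k_back) — the branching ratio that rectifies
    the Brownian excursion forward.
    """
    kc, kb = scheme.k_cat_exact, scheme.k_back_exact
    return 100.0 * kc / (kc + kb)


def equilibrium_and_deltaG(scheme: KineticScheme, T_kelvin: float = T_STANDARD_K) -> ThermoResult:
    """Forward/backward-state equilibrium constant and free-energy gap.

    K = k_dec / k_back; delta G = -R T ln K (kcal/mol), computed from the
    unrounded ratio.  K is additionally reported rounded to one decimal.
    """
    if T_kelvin <= 0:
        raise ValueError("temperature must be positive")
    K_raw = scheme.k_dec_exact / scheme.k_back_exact
    dG = -R_KCAL * T_kelvin * math.log(K_raw)
    return ThermoResult(
        K_eq_raw=K_raw, K_eq=round(K_raw, 1), delta_G_kcal_mol=dG, T_kelvin=T_kelvin
    )


def equilibrium_from_rates(k_dec_per_s: float, k_back_per_s: float,
                           T_kelvin: float = T_STANDARD_K) -> ThermoResult:
    """Same as :func:`equilibrium_and_deltaG` but from explicit rates."""
    if k_dec_per_s <= 0 or k_back_per_s <= 0:
        raise ValueError("rates must be positive")
    K_raw = k_dec_per_s / k_back_per_s
    dG = -R_KCAL * T_kelvin * math.log(K_raw)
    return ThermoResult(
        K_eq_raw=K_raw, K_eq=round(K_raw, 1), delta_G_kcal_mol=dG, T_kelvin=T_kelvin
    )


def mean_velocity(
    scheme: KineticScheme,
    step_ratios: Optional[dict] = None,
    step_size_nm: Optional[float] = None,
) -> float:
    """Closed-form mean velocity (nm/s) of the stepping chain.

    Matches the ratio-based simulator: per cycle a kind is chosen with the
    given probabilities (forward / double / backward; a backward step is
    always undone by a recovery), so

        v = E[displacement] / E[cycle time]
          = (q_f + 2 q_d) d / (q_f T_f1 + q_d T_f2 + q_b (T_b + T_rec))

    with T_f1 = tau_cat + tau_forward_long, T_f2 = tau_forward2,
    T_b = tau_back, T_rec = tau_dec.  With backward probability zero and
    no doubles this reduces to d / (tau_cat + tau_release + tau_dec).
    Serves as the independent oracle for simulated-ensemble velocities.
    """
    if step_ratios is None:
        step_ratios = {"forward": 1.0, "double": 0.0, "backward": 0.0}
    d = scheme.d_step_nm if step_size_nm is None else step_size_nm
    qf, qd, qb = (step_ratios[k] for k in ("forward", "double", "backward"))
    if abs(qf + qd + qb - 1.0) > 1e-9:
        raise ValueError("step ratios must sum to 1")
    if qd > 0 and scheme.tau_forward2_ms is None:
        raise ValueError("double-step ratio > 0 requires tau_forward2_ms")
    t_f1 = scheme.tau_cat_ms + scheme.tau_forward_long_ms
    t_f2 = scheme.tau_forward2_ms or 0.0
    t_bk = scheme.tau_back_ms + scheme.tau_dec_ms
    mean_disp_nm = (qf + 2.0 * qd) * d
    mean_time_ms = qf * t_f1 + qd * t_f2 + qb * t_bk
    return 1000.0 * mean_disp_nm / mean_time_ms


def kie_ratio(value_h2o: float, value_d2o: float, quantity: str = "time_constant") -> float:
    """Kinetic isotope effect as a slow-down fold >= 1 when present.

    For time constants the fold is tau_D2O / tau_H2O; for rates (kcat)
    it is k_H2O / k_D2O.
    """
    if value_h2o <= 0 or value_d2o <= 0:
        raise ValueError("both values must be positive")
    if quantity == "time_constant":
        return value_d2o / value_h2o
    if quantity in ("rate", "kcat"):
        return value_h2o / value_d2o
    raise ValueError("quantity must be 'time_constant' or 'rate'")


def processivity(mean_run_length_nm: float, d_step_nm: float = CHITOBIOSE_NM) -> int:
    """Number of catalytic turnovers per binding event, rounded to integer."""
    if mean_run_length_nm <= 0:
        raise ValueError("run length must be positive")
    return int(round(mean_run_length_nm / d_step_nm))
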