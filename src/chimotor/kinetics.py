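"""Bulk enzyme kinetics: Michaelis-Menten with substrate inhibition.

Soluble-substrate turnover of the enzyme follows

    v([S]) = kcat [S] / (Km + [S] + [S]^2 / Ksi)

where Ksi is the substrate-inhibition constant; the curve peaks at
[S] = sqrt(Km Ksi) and falls at higher concentrations.  Fitting this to
turnover tables measured in H2O and D2O gives the kcat ratio, the kinetic
isotope effect of the hydrolysis chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


def substrate_inhibition_rate(s_uM, kcat, km_uM, ksi_uM):
    """Model turnover (s^-1) at substrate concentration [S] (uM)."""
    s = np.asarray(s_uM, dtype=float)
    return kcat * s / (km_uM + s + s**2 / ksi_uM)


@dataclass
class MMFitResults:
    """Fitted substrate-inhibition parameters with asymptotic errors."""

    kcat_per_s: float
    km_uM: float
    ksi_uM: float
    bse: np.ndarray
    ksi_at_bound: bool
    n: int

    def predict(self, s_uM):
        return substrate_inhibition_rate(s_uM, self.kcat_per_s, self.km_uM, self.ksi_uM)

    def summary(self) -> str:
        lines = [
            f"Michaelis-Menten fit with substrate inhibition (n={self.n})",
            f"  kcat = {self.kcat_per_s:.3g} +/- {self.bse[0]:.2g} s^-1",
            f"  Km   = {self.km_uM:.3g} +/- {self.bse[1]:.2g} uM",
        ]
        if self.ksi_at_bound:
            lines.append(f"  Ksi  > {self.ksi_uM:.3g} uM (no inhibition detectable; lower bound)")
        else:
            lines.append(f"  Ksi  = {self.ksi_uM:.3g} +/- {self.bse[2]:.2g} uM")
        return "\n".join(lines)


class SubstrateInhibitionModel:
    """Least-squares fit of the substrate-inhibition rate law.

    Parameters
    ----------
    conc_uM, rate_per_s : arrays
        Substrate concentrations (uM) and measured turnovers (s^-1);
        at least 5 concentrations spanning below Km and above
        sqrt(Km Ksi) are needed for all three parameters to be resolved.
    """

    #: inverse-Ksi below this (uM^-1) is treated as "no inhibition detectable"
    _INV_KSI_FLOOR = 1e-8

    def __init__(self, conc_uM, rate_per_s) -> None:
        self.s = np.asarray(conc_uM, dtype=float)
        self.v = np.asarray(rate_per_s, dtype=float)
        if len(self.s) != len(self.v):
            raise ValueError("conc and rate must have equal length")
        if len(self.s) < 5:
            raise ValueError("need at least 5 concentrations")
        if np.any(self.s <= 0):
            raise ValueError("concentrations must be positive")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SubstrateInhibitionModel":
        return cls(df["conc_uM"].to_numpy(), df["rate_per_s"].to_numpy())

    def fit(self) -> MMFitResults:
        vmax = float(np.max(self.v))
        s_at_max = float(self.s[np.argmax(self.v)])
        # parameterize inhibition as 1/Ksi >= 0 so "no inhibition" sits at a finite bound
        def model(s, kcat, km, inv_ksi):
            return kcat * s / (km + s + s**2 * inv_ksi)

        p0 = [2.0 * vmax, s_at_max, 1.0 / (10.0 * np.max(self.s))]
        popt, pcov = curve_fit(
            model,
            self.s,
            self.v,
            p0=p0,
            bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
            xtol=1e-12,
            ftol=1e-12,
        )
        bse = np.sqrt(np.diag(pcov))
        inv_ksi = popt[2]
        # no detectable inhibition: 1/Ksi at its zero bound or swamped by
        # its own standard error
        at_bound = inv_ksi < max(self._INV_KSI_FLOOR, 2.0 * bse[2])
        ksi = (1.0 / self._INV_KSI_FLOOR) if at_bound else 1.0 / inv_ksi
        ksi_err = np.inf if at_bound else bse[2] / inv_ksi**2
        return MMFitResults(
            kcat_per_s=float(popt[0]),
            km_uM=float(popt[1]),
            ksi_uM=float(ksi),
            bse=np.array([bse[0], bse[1], ksi_err]),
            ksi_at_bound=bool(at_bound),
            n=len(self.s),
        )


def fit_mm_substrate_inhibition(conc_uM, rate_per_s) -> MMFitResults:
    """Functional wrapper around :class:`SubstrateInhibitionModel`."""
    return SubstrateInhibitionModel(conc_uM, rate_per_s).fit()
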