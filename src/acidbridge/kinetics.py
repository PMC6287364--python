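"""Inactivation and steady-state kinetics: half-lives and Hanes–Woolf fits.

First-order inactivation is fitted as a linear regression of the natural
log of residual activity on incubation time; the rate constant ``kd`` is
minus the slope and the half-life is t1/2 = ln2/kd.  Michaelis–Menten
parameters come from the Hanes–Woolf linearisation (regress S/v on S:
slope 1/Vmax, intercept KM/Vmax), which is the classical
spectrophotometry-era estimator; a nonlinear least-squares fit is provided
as a cross-check.  Units are explicit: minutes for inactivation, seconds
for turnover, uM for concentrations, and catalytic efficiency kcat/KM in
s^-1 mM^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DecayFit",
    "MMFit",
    "AbsorbanceParams",
    "fit_first_order_decay",
    "fit_hanes_woolf",
    "fit_michaelis_menten",
    "catalytic_efficiency",
    "rate_from_absorbance",
    "load_table",
]


@dataclass
class DecayFit:
    """First-order inactivation fit: kd in 1/min, half-life in min."""

    kd: float
    t_half: float
    r_squared: float
    n_points: int
    no_decay: bool = False


@dataclass
class MMFit:
    """Michaelis–Menten parameters with km in uM, vmax in uM/s, kcat in 1/s."""

    km: float
    vmax: float
    kcat: float
    efficiency: float       # s^-1 mM^-1
    km_se: float
    vmax_se: float
    n_points: int
    valid: bool = True


@dataclass
class AbsorbanceParams:
    """Beer–Lambert conversion constants."""

    extinction: float       # mM^-1 cm^-1
    pathlength: float = 1.0  # cm
    wavelength: float | None = None   # nm, informational

    def __post_init__(self) -> None:
        if self.extinction <= 0 or self.pathlength <= 0:
            raise ValueError("extinction and pathlength must be positive")


def _columns(table, names: tuple[str, str]) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(table, pd.DataFrame):
        cols = list(table.columns)
        return (
            np.asarray(table[cols[0]], dtype=float),
            np.asarray(table[cols[1]], dtype=float),
        )
    arr = np.asarray(table, dtype=float)
    return arr[:, 0], arr[:, 1]


def fit_first_order_decay(table) -> DecayFit:
    """Fit ln(residual activity) against time by ordinary least squares.

    ``table`` is a two-column DataFrame or array of (time in minutes,
    activity).  Activities must be positive; with a non-negative slope the
    fit is flagged ``no_decay`` and the half-life reported as +inf.
    """
    t, a = _columns(table, ("time_min", "activity"))
    if t.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(a <= 0):
        raise ValueError("activities must be positive to take logarithms")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    res = stats.linregress(t, np.log(a))
    kd = -res.slope
    if kd <= 0:
        return DecayFit(kd=kd, t_half=math.inf, r_squared=res.rvalue ** 2,
                        n_points=t.size, no_decay=True)
    return DecayFit(kd=kd, t_half=math.log(2.0) / kd, r_squared=res.rvalue ** 2,
                    n_points=t.size)


def fit_hanes_woolf(table, enzyme_conc: float) -> MMFit:
    """Hanes–Woolf estimate of KM and kcat from an initial-rate table.

    ``table`` holds (substrate in uM, rate in uM/s); ``enzyme_conc`` is in
    uM.  Regressing S/v on S gives slope 1/Vmax and intercept KM/Vmax.
    Standard errors are propagated from the regression coefficients
    (covariance ignored in the KM ratio, reported as indicative).
    """
    if enzyme_conc <= 0:
        raise ValueError("enzyme_conc must be positive")
    s, v = _columns(table, ("substrate_uM", "rate_uM_per_s"))
    if np.unique(s[s > 0]).size < 3:
        raise ValueError("need at least 3 distinct positive substrate levels")
    if np.any(s <= 0) or np.any(v <= 0):
        raise ValueError("substrate levels and rates must be positive")
    res = stats.linregress(s, s / v)
    slope, intercept = res.slope, res.intercept
    valid = slope > 0 and intercept > 0
    vmax = 1.0 / slope if slope > 0 else math.nan
    km = intercept / slope if valid else math.nan
    kcat = vmax / enzyme_conc
    vmax_se = res.stderr / slope ** 2 if slope > 0 else math.nan
    km_se = (
        abs(km) * math.hypot(res.stderr / slope, res.intercept_stderr / intercept)
        if valid else math.nan
    )
    return MMFit(
        km=km, vmax=vmax, kcat=kcat,
        efficiency=catalytic_efficiency(kcat, km) if valid else math.nan,
        km_se=km_se, vmax_se=vmax_se, n_points=s.size, valid=valid,
    )


def fit_michaelis_menten(table, enzyme_conc: float) -> MMFit:
    """Nonlinear least-squares Michaelis–Menten fit (cross-check estimator)."""
    if enzyme_conc <= 0:
        raise ValueError("enzyme_conc must be positive")
    s, v = _columns(table, ("substrate_uM", "rate_uM_per_s"))
    if np.unique(s[s > 0]).size < 3:
        raise ValueError("need at least 3 distinct positive substrate levels")

    def mm(s, vmax, km):
        return vmax * s / (km + s)

    p0 = (float(v.max()), float(np.median(s)))
    popt, pcov = optimize.curve_fit(mm, s, v, p0=p0, maxfev=10000)
    vmax, km = float(popt[0]), float(popt[1])
    se = np.sqrt(np.diag(pcov))
    valid = vmax > 0 and km > 0
    kcat = vmax / enzyme_conc
    return MMFit(
        km=km, vmax=vmax, kcat=kcat,
        efficiency=catalytic_efficiency(kcat, km) if valid else math.nan,
        km_se=float(se[1]), vmax_se=float(se[0]), n_points=s.size, valid=valid,
    )


def catalytic_efficiency(kcat: float, km_um: float) -> float:
    """kcat/KM in s^-1 mM^-1 from kcat in s^-1 and KM in uM."""
    if km_um <= 0:
        raise ValueError("KM must be positive")
    return kcat / (km_um / 1000.0)


def rate_from_absorbance(da_per_min: float, params: AbsorbanceParams) -> float:
    """Convert an absorbance slope (1/min) to a rate in uM/min.

    Beer–Lambert: rate = dA/dt / (extinction * pathlength), with the mM
    extinction coefficient giving mM/min, scaled by 1000 to uM/min.
    """
    return da_per_min / (params.extinction * params.pathlength) * 1000.0


def load_table(path) -> pd.DataFrame:
    """Read a delimited (time, activity) or (substrate, rate) table with header."""
    return pd.read_csv(path)
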