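"""Weibull dissolution kinetics, profile fitting, and f2 similarity.

The in vitro release of each tablet component is described empirically by a
Weibull cumulative-release curve,

    F(t) = 1 - exp(-ln 2 * ((t - tlag) / td50) ** shape),   t > tlag,

parameterised directly by the time ``td50`` at which 50% of the dose has
dissolved (measured from the end of the lag), the dimensionless ``shape``
controlling the curvature (1 = first-order release; >1 sigmoid), and an
optional lag ``tlag``.  This reparameterisation makes published
"50% dissolved time" values usable verbatim: the conventional Weibull scale
parameter is ``a = td50**shape / ln 2``, and F(tlag + td50) = 0.5 exactly for
any shape.

The hazard form ``h(t) = f(t) / (1 - F(t))`` is the instantaneous first-order
release-rate constant the absorption ODE engine applies to the undissolved
solid pool; integrating ``dS/dt = -h(t) S`` from a unit pool reproduces
``1 - F(t)`` exactly whenever no solubility cap intervenes.

Profile similarity uses the regulatory f2 statistic,

    f2 = 50 * log10( 100 / sqrt(1 + mean((R_i - T_i)**2)) ),

computed on a shared time grid after the standard subsetting (at most one
point retained after both profiles exceed 85% dissolved).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.optimize import least_squares

LN2 = math.log(2.0)

__all__ = [
    "WeibullParams",
    "DissolutionProfile",
    "FitDiagnostics",
    "weibull_fraction",
    "weibull_hazard",
    "fit_weibull",
    "f2_similarity",
]


class WeibullParams(BaseModel):
    """Weibull release kinetics of one formulation.

    Attributes
    ----------
    td50 : float
        Minutes after the lag at which 50% of the dose is dissolved (> 0).
    shape : float
        Dimensionless curvature parameter (> 0).
    tlag : float
        Lag time in minutes before release starts (>= 0).
    """

    td50: float = Field(gt=0)
    shape: float = Field(gt=0)
    tlag: float = Field(default=0.0, ge=0)

    @property
    def scale_a(self) -> float:
        """Conventional Weibull scale parameter ``a = td50**shape / ln 2``."""
        return self.td50**self.shape / LN2


class DissolutionProfile(BaseModel):
    """One measured (or synthetic) dissolution profile in one medium."""

    times: list[float]
    pct_dissolved: list[float]
    medium_ph: float
    label: str = ""

    @model_validator(mode="after")
    def _check(self) -> "DissolutionProfile":
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.pct_dissolved, dtype=float)
        if t.size != y.size or t.size < 3:
            raise ValueError("need >= 3 paired (time, pct) points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError("times and pct_dissolved must be finite")
        if np.any(y < 0) or np.any(y > 110):
            raise ValueError("pct_dissolved must lie in [0, 110]")
        return self

    @property
    def times_arr(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    @property
    def pct_arr(self) -> np.ndarray:
        return np.asarray(self.pct_dissolved, dtype=float)


def weibull_fraction(t, p: WeibullParams):
    """Fraction of dose dissolved at time ``t`` (minutes).

    Vectorised over ``t``; returns 0 for ``t <= tlag`` and approaches 1 as
    ``t`` grows.  Monotone nondecreasing in ``t``.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    x = np.maximum(t - p.tlag, 0.0)
    out = 1.0 - np.exp(-LN2 * (x / p.td50) ** p.shape)
    return out if out.ndim else float(out)


def weibull_hazard(t, p: WeibullParams):
    """Instantaneous release-rate constant h(t) = f(t)/(1-F(t)) in 1/min.

    Zero for ``t <= tlag``.  Note h diverges at ``t -> tlag+`` when
    ``shape < 1``; the ODE engine caps it numerically.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    x = t - p.tlag
    pos = x > 0
    out = np.zeros_like(x)
    with np.errstate(divide="ignore"):
        out[pos] = LN2 * p.shape / p.td50 * (x[pos] / p.td50) ** (p.shape - 1.0)
    return out if out.ndim else float(out)


@dataclass
class FitDiagnostics:
    rss: float
    r2: float
    fitted_pct: np.ndarray
    start_values: list[tuple[float, float]]
    converged: bool


def _initial_td50(times: np.ndarray, pct: np.ndarray) -> float:
    # time of the observation nearest 50% dissolved, clipped to the grid
    idx = int(np.argmin(np.abs(pct - 50.0)))
    return max(float(times[idx]), 1e-3)


def fit_weibull(
    profile: DissolutionProfile,
    weighting: Literal["none", "relative"] = "none",
    fit_tlag: bool = False,
) -> tuple[WeibullParams, FitDiagnostics]:
    """Least-squares Weibull fit of a dissolution profile.

    Bounded nonlinear least squares on (td50, shape[, tlag]) with multi-start
    (td50 near the 50%-dissolved observation; shape in {0.7, 1.0, 2.0}) to
    dodge local minima.  ``tlag`` is held at 0 unless ``fit_tlag``.

    Returns the best parameters and diagnostics (RSS, R^2, fitted curve).
    Raises ``ValueError`` for an all-zero profile and ``RuntimeError`` (with
    the starting values tried) if no start converges.
    """
    t = profile.times_arr
    y = profile.pct_arr
    if np.all(y <= 0):
        raise ValueError("all-zero dissolution profile cannot be fitted")
    post = y > 0
    if np.count_nonzero(post) < 3:
        raise ValueError("need >= 3 post-lag points with nonzero dissolution")

    w = np.ones_like(y) if weighting == "none" else 1.0 / np.maximum(y, 1.0)

    td50_0 = _initial_td50(t, y)
    starts = [(td50_0, s) for s in (1.0, 0.7, 2.0)]

    def residuals(theta: np.ndarray) -> np.ndarray:
        if fit_tlag:
            p = WeibullParams(td50=theta[0], shape=theta[1], tlag=theta[2])
        else:
            p = WeibullParams(td50=theta[0], shape=theta[1])
        return w * (100.0 * weibull_fraction(t, p) - y)

    lo = [1e-4, 1e-2] + ([0.0] if fit_tlag else [])
    hi = [1e5, 20.0] + ([float(t[-1])] if fit_tlag else [])

    best = None
    for td0, sh0 in starts:
        x0 = [td0, sh0] + ([0.0] if fit_tlag else [])
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if not sol.success:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(f"Weibull fit failed to converge from starts {starts}")

    theta = best.x
    params = WeibullParams(
        td50=theta[0], shape=theta[1], tlag=theta[2] if fit_tlag else 0.0
    )
    fitted = 100.0 * weibull_fraction(t, params)
    rss = float(np.sum((fitted - y) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss < 1e-12 else 0.0)
    diag = FitDiagnostics(
        rss=rss, r2=r2, fitted_pct=fitted, start_values=starts, converged=True
    )
    return params, diag


def _f2_usable_mask(ref: np.ndarray, test: np.ndarray) -> np.ndarray:
    """Standard guidance subsetting: keep at most one point after both
    profiles exceed 85% dissolved."""
    both_above = (ref > 85.0) & (test > 85.0)
    mask = np.ones(ref.size, dtype=bool)
    idx = np.nonzero(both_above)[0]
    if idx.size > 1:
        mask[idx[1]:] = False
    return mask


def f2_similarity(ref: DissolutionProfile, test: DissolutionProfile) -> float:
    """Regulatory f2 similarity factor between two profiles.

    Profiles must share an identical time grid.  Symmetric in its arguments;
    identical profiles give 100.  Raises on mismatched grids or fewer than
    3 usable points after the >85% subsetting.
    """
    tr, tt = ref.times_arr, test.times_arr
    if tr.size != tt.size or not np.allclose(tr, tt):
        raise ValueError("dissolution profiles must share identical time points")
    r, s = ref.pct_arr, test.pct_arr
    mask = _f2_usable_mask(r, s)
    if np.count_nonzero(mask) < 3:
        raise ValueError("fewer than 3 usable points for f2 after 85% subsetting")
    msd = float(np.mean((r[mask] - s[mask]) ** 2))
    return 50.0 * math.log10(100.0 / math.sqrt(1.0 + msd))
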