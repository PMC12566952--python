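"""Non-compartmental analysis, validation metrics, and 2x2 crossover BE statistics.

NCA reduces a plasma curve to Cmax (maximum concentration), Tmax (first time
attaining it) and AUC0-t (linear trapezoid to the last sampling time).

Model validation uses the conventional fold error FE = predicted/observed and
prediction error PE = |predicted - observed|/observed, with acceptance
thresholds FE <= 2 and PE <= 20%; note PE = |FE - 1| identically.

Bioequivalence uses the standard fixed-effects crossover ANOVA on the
log-transformed metric (treatment + period + subject effects; for a balanced
complete 2x2 design this coincides with the paired analysis of period
differences).  The 90% confidence interval of the geometric mean ratio is
exp(delta_hat +/- t_{0.05, n-2} * SE) expressed in percent, and equivalence
(two one-sided tests) passes iff the CI lies within [80.00, 125.00]%.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PKMetrics",
    "ValidationMetrics",
    "BEResult",
    "BE_BOUNDS_PCT",
    "nca_metrics",
    "prediction_error",
    "fold_error",
    "validation_metrics",
    "gmr_ratio_percent",
    "be_crossover_analysis",
]

BE_BOUNDS_PCT = (80.00, 125.00)


@dataclass
class PKMetrics:
    cmax: float  # ng/mL
    tmax: float  # h
    auc_0t: float  # ng*h/mL

    def get(self, name: str) -> float:
        return {"cmax": self.cmax, "tmax": self.tmax, "auc_0t": self.auc_0t}[name]


@dataclass
class ValidationMetrics:
    fe: float
    pe: float

    @property
    def pass_fe(self) -> bool:
        return self.fe <= 2.0

    @property
    def pass_pe(self) -> bool:
        return self.pe <= 0.20


@dataclass
class BEResult:
    metric: str
    gmr_pct: float
    ci90: tuple[float, float]
    n_subjects: int

    @property
    def passed(self) -> bool:
        lo, hi = self.ci90
        return BE_BOUNDS_PCT[0] <= lo and hi <= BE_BOUNDS_PCT[1]

    def summary(self) -> dict:
        return {
            "metric": self.metric,
            "gmr_pct": round(self.gmr_pct, 2),
            "ci90_low_pct": round(self.ci90[0], 2),
            "ci90_high_pct": round(self.ci90[1], 2),
            "pass": self.passed,
            "n": self.n_subjects,
        }


def nca_metrics(times_h, conc) -> PKMetrics:
    """Cmax / Tmax / AUC0-t by linear trapezoid from a sampled curve."""
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("need >= 2 strictly increasing time points")
    if np.any(c < 0):
        raise ValueError("negative concentrations")
    if np.all(c == 0):
        warnings.warn("all-zero concentration profile; metrics are zero")
        return PKMetrics(cmax=0.0, tmax=float(t[0]), auc_0t=0.0)
    imax = int(np.argmax(c))
    return PKMetrics(
        cmax=float(c[imax]),
        tmax=float(t[imax]),
        auc_0t=float(np.trapezoid(c, t)),
    )


def prediction_error(predicted: float, observed: float) -> float:
    """PE = |predicted - observed| / observed."""
    if observed <= 0:
        raise ValueError("observed must be > 0")
    return abs(predicted - observed) / observed


def fold_error(predicted: float, observed: float) -> float:
    """FE = predicted / observed."""
    if observed <= 0:
        raise ValueError("observed must be > 0")
    return predicted / observed


def validation_metrics(predicted: float, observed: float) -> ValidationMetrics:
    return ValidationMetrics(
        fe=fold_error(predicted, observed), pe=prediction_error(predicted, observed)
    )


def gmr_ratio_percent(t_value: float, r_value: float) -> float:
    """Test/reference ratio in percent, rounded to 2 decimals for reporting."""
    if t_value <= 0 or r_value <= 0:
        raise ValueError("both values must be > 0")
    return round(100.0 * t_value / r_value, 2)


def be_crossover_analysis(
    design_table: pd.DataFrame,
    metrics: pd.DataFrame,
    metric: str,
) -> BEResult:
    """TOST bioequivalence analysis of one metric in a 2x2 crossover.

    Parameters
    ----------
    design_table : DataFrame with subject_id, sequence, period, treatment.
    metrics : DataFrame with subject_id, period and a column named ``metric``
        (cmax or auc_0t) holding the per-cell value.
    metric : which metric column to analyse.

    Subjects missing a period are dropped with a warning; fewer than 3
    subjects per sequence is an error.  The treatment effect and its SE come
    from the fixed-effects OLS fit of log(metric) on treatment, period and
    subject indicators (residual df = n - 2 for a complete balanced design).
    """
    if metric not in metrics.columns:
        raise ValueError(f"metrics table lacks column {metric!r}")
    df = design_table.merge(
        metrics[["subject_id", "period", metric]], on=["subject_id", "period"]
    )
    counts = df.groupby("subject_id")["period"].nunique()
    incomplete = counts[counts < 2].index
    if len(incomplete) > 0:
        warnings.warn(f"dropping {len(incomplete)} subject(s) missing a period")
        df = df[~df["subject_id"].isin(incomplete)]
    seq_n = df.drop_duplicates("subject_id").groupby("sequence").size()
    if seq_n.min() < 3 or len(seq_n) < 2:
        raise ValueError("need >= 3 subjects per sequence")
    if np.any(df[metric] <= 0):
        raise ValueError("metric values must be > 0 for log analysis")

    n = df["subject_id"].nunique()
    y = np.log(df[metric].to_numpy())
    # design matrix: intercept, treatment(T), period(2), subject dummies
    treat = (df["treatment"] == "T").to_numpy(dtype=float)
    per2 = (df["period"] == 2).to_numpy(dtype=float)
    subj_ids = df["subject_id"].to_numpy()
    uniq = np.unique(subj_ids)
    S = (subj_ids[:, None] == uniq[None, 1:]).astype(float)  # drop first level
    X = np.column_stack([np.ones(len(df)), treat, per2, S])

    import statsmodels.api as sm

    fit = sm.OLS(y, X).fit()
    delta = float(fit.params[1])
    se = float(fit.bse[1])
    dof = int(fit.df_resid)
    if not np.isfinite(se) or se <= 0 or dof <= 0:
        # degenerate (e.g. T identical to R within every subject)
        lo = hi = math.exp(delta) * 100.0
    else:
        tcrit = stats.t.ppf(0.95, dof)
        lo = math.exp(delta - tcrit * se) * 100.0
        hi = math.exp(delta + tcrit * se) * 100.0
    return BEResult(
        metric=metric,
        gmr_pct=math.exp(delta) * 100.0,
        ci90=(lo, hi),
        n_subjects=n,
    )
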