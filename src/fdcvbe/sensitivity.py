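"""Local sensitivity analysis, the virtual-BE driver, and the dissolution
safe-space search.

Sensitivity uses the dimensionless local relative coefficient

    S = (dPK / dP) * (P / PK)  =  (relative output change) / (relative input change),

estimated one-at-a-time with a +10% relative step by default (optionally the
central average of +/-10%).  Parameters with |S| < 0.05 for every output are
flagged as excluded from downstream population variability.

The VBE driver simulates every (subject, period, treatment) cell of a 2x2
crossover with the subject's period-specific GI state and the population
disposition, reduces each cell to NCA metrics, and applies the crossover
TOST analysis per metric.  The fixed-dose-combination verdict requires Cmax
and AUC0-t to pass for every component.

The safe-space search varies the test formulation's 50%-dissolution time
over a grid (coarse 5-min scan, then bisection to 1-min resolution at each
pass/fail transition) while the reference arm, the virtual population and
the design stay fixed, and reports the outermost passing td50 values.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .absorption import DrugParameters, GIPhysiology
from .dissolution import WeibullParams
from .engine import DispositionParams, SimulationConfig, assemble_odes, simulate_subject
from .pkstats import BEResult, be_crossover_analysis, nca_metrics
from .population import CrossoverDesign, VirtualSubject

__all__ = [
    "SensitivityResult",
    "SafeSpaceResult",
    "VBEOutcome",
    "sensitivity_coefficient",
    "run_sensitivity",
    "run_vbe",
    "fdc_verdict",
    "explore_safe_space",
]

SENSITIVITY_THRESHOLD = 0.05


@dataclass
class SensitivityResult:
    parameter: str
    output: str
    s: float
    included: bool
    failed: bool = False


def sensitivity_coefficient(
    pk_base: float, pk_pert: float, p_base: float, p_pert: float
) -> float:
    """Local relative sensitivity S = (dPK/dP) * (P/PK)."""
    if pk_base <= 0 or p_base <= 0:
        raise ValueError("baseline values must be > 0")
    if p_pert == p_base:
        raise ValueError("perturbed parameter equals baseline")
    return (pk_pert - pk_base) / (p_pert - p_base) * (p_base / pk_base)


def _get_path(obj, path: str):
    cur = obj
    for part in path.split("."):
        cur = cur[part] if isinstance(cur, dict) else getattr(cur, part)
    return cur


def _set_path(obj, path: str, value) -> None:
    parts = path.split(".")
    cur = obj
    for part in parts[:-1]:
        cur = cur[part] if isinstance(cur, dict) else getattr(cur, part)
    last = parts[-1]
    if isinstance(cur, dict):
        cur[last] = value
    else:
        setattr(cur, last, value)


def perturb_config(cfg: SimulationConfig, path: str, factor: float) -> SimulationConfig:
    """Deep-copied config with the dotted-path parameter scaled by ``factor``.

    Paths address the nested model, e.g. ``phys.sitt``,
    ``phys.segment_ph.jejunum``, ``disp.cl_hepatic``, ``drug.peff_trans``.
    """
    new = copy.deepcopy(cfg)
    base = _get_path(new, path)
    if not isinstance(base, (int, float)):
        raise TypeError(f"parameter at {path!r} is not numeric")
    _set_path(new, path, float(base) * factor)
    return new


def run_sensitivity(
    cfg: SimulationConfig,
    parameters: Sequence[str],
    step: float = 0.10,
    outputs: Sequence[str] = ("cmax", "auc_0t", "tmax"),
    central: bool = False,
    threshold: float = SENSITIVITY_THRESHOLD,
) -> pd.DataFrame:
    """One-at-a-time local sensitivity table.

    Simulates the baseline once, perturbs each dotted-path parameter by
    ``+step`` relative (and ``-step`` as well when ``central``), and reports
    the relative sensitivity coefficient per output, ranked by max |S|.
    A simulation failure marks that parameter's rows failed and the run
    continues.
    """
    base_prof = cfg.simulate()
    base_pk = nca_metrics(base_prof.times, base_prof.conc)

    rows: list[SensitivityResult] = []
    for path in parameters:
        p0 = float(_get_path(cfg, path))
        try:
            up = perturb_config(cfg, path, 1.0 + step).simulate()
            pk_up = nca_metrics(up.times, up.conc)
            if central:
                dn = perturb_config(cfg, path, 1.0 - step).simulate()
                pk_dn = nca_metrics(dn.times, dn.conc)
        except (RuntimeError, ValueError):
            for out in outputs:
                rows.append(SensitivityResult(path, out, np.nan, False, failed=True))
            continue
        for out in outputs:
            base_val = base_pk.get(out)
            if base_val <= 0:
                rows.append(SensitivityResult(path, out, np.nan, False, failed=True))
                continue
            s_up = sensitivity_coefficient(
                base_val, pk_up.get(out), p0, p0 * (1.0 + step)
            )
            if central:
                s_dn = sensitivity_coefficient(
                    base_val, pk_dn.get(out), p0, p0 * (1.0 - step)
                )
                s = 0.5 * (s_up + s_dn)
            else:
                s = s_up
            rows.append(SensitivityResult(path, out, s, abs(s) >= threshold))

    df = pd.DataFrame([r.__dict__ for r in rows])
    rank = (
        df.groupby("parameter")["s"]
        .apply(lambda x: np.nanmax(np.abs(x)) if np.any(np.isfinite(x)) else -np.inf)
        .rank(ascending=False, method="first")
    )
    df["rank"] = df["parameter"].map(rank).astype(int)
    return df.sort_values(["rank", "parameter", "output"]).reset_index(drop=True)


@dataclass
class VBEOutcome:
    drug: str
    results: dict[str, BEResult]  # metric -> BEResult
    metrics_table: pd.DataFrame  # per subject-period NCA

    @property
    def passed(self) -> bool:
        return all(r.passed for r in self.results.values())


def _simulate_cells(
    subjects: list[VirtualSubject],
    design: CrossoverDesign,
    drug: DrugParameters,
    dose_mg: float,
    forms: dict[str, WeibullParams],
    treatments: Iterable[str] = ("T", "R"),
    rtol: float = 1e-6,
    atol: float = 1e-8,
    n_out: int = 289,
) -> pd.DataFrame:
    """NCA metrics for every (subject, period) cell of the given treatments."""
    by_id = {s.id: s for s in subjects}
    wanted = set(treatments)
    rows = []
    for rec in design.table.itertuples(index=False):
        if rec.treatment not in wanted:
            continue
        subj = by_id[rec.subject_id]
        phys = subj.gi_state_1 if rec.gi_state == 1 else subj.gi_state_2
        system = assemble_odes(
            drug, forms[rec.treatment], phys, subj.disposition, dose_mg
        )
        try:
            prof = simulate_subject(system, rtol=rtol, atol=atol, n_out=n_out)
        except RuntimeError as err:
            raise RuntimeError(
                f"simulation failed for subject {rec.subject_id}, period "
                f"{rec.period}, treatment {rec.treatment}: {err}"
            ) from err
        pk = nca_metrics(prof.times, prof.conc)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "sequence": rec.sequence,
                "period": rec.period,
                "treatment": rec.treatment,
                "cmax": pk.cmax,
                "tmax": pk.tmax,
                "auc_0t": pk.auc_0t,
            }
        )
    return pd.DataFrame(rows)


def run_vbe(
    subjects: list[VirtualSubject],
    design: CrossoverDesign,
    drug: DrugParameters,
    dose_mg: float,
    test_form: WeibullParams,
    ref_form: WeibullParams,
    metrics: Sequence[str] = ("cmax", "auc_0t"),
    rtol: float = 1e-6,
    atol: float = 1e-8,
    n_out: int = 289,
) -> VBEOutcome:
    """Virtual bioequivalence of test vs reference for one component.

    Deterministic given the subjects and design (no randomness enters the
    simulation itself).
    """
    forms = {"T": test_form, "R": ref_form}
    table = _simulate_cells(
        subjects, design, drug, dose_mg, forms, rtol=rtol, atol=atol, n_out=n_out
    )
    results = {
        m: be_crossover_analysis(design.table, table, m) for m in metrics
    }
    return VBEOutcome(drug=drug.name, results=results, metrics_table=table)


def fdc_verdict(outcomes: Iterable[VBEOutcome]) -> bool:
    """The combination passes only if every metric of every component passes."""
    return all(o.passed for o in outcomes)


@dataclass
class SafeSpacePoint:
    td50: float
    results: dict[str, BEResult]

    @property
    def passed(self) -> bool:
        return all(r.passed for r in self.results.values())


@dataclass
class SafeSpaceResult:
    drug: str
    points: list[SafeSpacePoint]  # sorted by td50
    lower_bound_td50: float | None  # outermost passing td50 (None: empty space)
    upper_bound_td50: float | None
    lower_open: bool  # pass region reaches the scanned range edge
    upper_open: bool
    contiguous: bool

    def grid(self) -> pd.DataFrame:
        rows = []
        for p in self.points:
            row = {"td50": p.td50, "pass": p.passed}
            for m, r in p.results.items():
                row[f"{m}_gmr"] = r.gmr_pct
                row[f"{m}_lo"] = r.ci90[0]
                row[f"{m}_hi"] = r.ci90[1]
            rows.append(row)
        return pd.DataFrame(rows).sort_values("td50").reset_index(drop=True)


def explore_safe_space(
    subjects: list[VirtualSubject],
    design: CrossoverDesign,
    drug: DrugParameters,
    dose_mg: float,
    ref_form: WeibullParams,
    shape: float,
    td50_range: tuple[float, float],
    tlag: float = 0.0,
    coarse_step: float = 5.0,
    resolution: float = 1.0,
    metrics: Sequence[str] = ("cmax", "auc_0t"),
    rtol: float = 1e-6,
    atol: float = 1e-8,
    n_out: int = 289,
) -> SafeSpaceResult:
    """Scan the test product's td50 for the region that stays bioequivalent.

    The reference arm is simulated once and reused for every scan point, so
    differences across the grid are formulation-driven only; shape and lag
    of the virtual test batches are held fixed.  The scanned range must
    bracket the reference td50.
    """
    lo, hi = td50_range
    if not lo < ref_form.td50 < hi:
        raise ValueError("td50 search range must bracket the reference td50")

    # reference-arm metrics, computed once
    ref_table = _simulate_cells(
        subjects, design, drug, dose_mg, {"R": ref_form}, treatments=("R",),
        rtol=rtol, atol=atol, n_out=n_out,
    )

    def evaluate(td50: float) -> SafeSpacePoint:
        tform = WeibullParams(td50=td50, shape=shape, tlag=tlag)
        t_table = _simulate_cells(
            subjects, design, drug, dose_mg, {"T": tform}, treatments=("T",),
            rtol=rtol, atol=atol, n_out=n_out,
        )
        table = pd.concat([ref_table, t_table], ignore_index=True)
        results = {m: be_crossover_analysis(design.table, table, m) for m in metrics}
        return SafeSpacePoint(td50=td50, results=results)

    grid = list(np.arange(lo, hi + 1e-9, coarse_step))
    if ref_form.td50 not in grid:
        grid.append(ref_form.td50)
    grid = sorted(set(round(g, 6) for g in grid))
    points = {g: evaluate(g) for g in grid}

    # bisection at each pass/fail transition, to `resolution` minutes
    ordered = sorted(points)
    for a, b in zip(ordered[:-1], ordered[1:]):
        pa, pb = points[a].passed, points[b].passed
        x, y = a, b
        if pa == pb:
            continue
        while y - x > resolution:
            mid = round((x + y) / 2.0, 6)
            if mid in points:
                break
            pm = points[mid] = evaluate(mid)
            if pm.passed == points[x].passed:
                x = mid
            else:
                y = mid
    pts = [points[k] for k in sorted(points)]

    passing = [p.td50 for p in pts if p.passed]
    if not passing:
        return SafeSpaceResult(
            drug=drug.name, points=pts, lower_bound_td50=None,
            upper_bound_td50=None, lower_open=False, upper_open=False,
            contiguous=True,
        )
    lower, upper = min(passing), max(passing)
    # contiguity: every evaluated point between the outer passing bounds passes
    inner = [p for p in pts if lower <= p.td50 <= upper]
    contiguous = all(p.passed for p in inner)
    return SafeSpaceResult(
        drug=drug.name,
        points=pts,
        lower_bound_td50=lower,
        upper_bound_td50=upper,
        lower_open=bool(pts[0].passed),
        upper_open=bool(pts[-1].passed),
        contiguous=contiguous,
    )
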