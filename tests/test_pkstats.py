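"""NCA, validation metrics, ratio arithmetic, and crossover BE statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fdcvbe.pkstats import (
    be_crossover_analysis,
    fold_error,
    gmr_ratio_percent,
    nca_metrics,
    prediction_error,
    validation_metrics,
)


class TestNCA:
    def test_constant_profile(self):
        pk = nca_metrics([0, 1, 2, 4], [3.0, 3.0, 3.0, 3.0])
        assert pk.cmax == 3.0 and pk.tmax == 0.0
        assert pk.auc_0t == pytest.approx(12.0)

    def test_triangle_geometry(self):
        T, c = 8.0, 10.0
        pk = nca_metrics([0, T / 2, T], [0.0, c, 0.0])
        assert pk.auc_0t == pytest.approx(c * T / 2)
        assert pk.tmax == T / 2

    def test_single_spike_hand_sum(self):
        # trapezoid: two adjacent panels around the lone nonzero point
        pk = nca_metrics([0, 1, 2, 3, 4], [0, 0, 6.0, 0, 0])
        assert pk.auc_0t == pytest.approx(0.5 * 6 + 0.5 * 6)

    def test_piecewise_linear_exact(self):
        t = np.array([0, 0.5, 1.0, 2.0, 4.0, 8.0])
        c = np.array([0.0, 4.0, 6.0, 5.0, 2.0, 0.5])
        # trapezoid is exact for piecewise-linear curves
        exact = sum(
            (c[i] + c[i + 1]) / 2 * (t[i + 1] - t[i]) for i in range(len(t) - 1)
        )
        assert nca_metrics(t, c).auc_0t == pytest.approx(exact, rel=1e-12)

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning):
            pk = nca_metrics([0, 1, 2], [0, 0, 0])
        assert pk.cmax == 0.0 and pk.auc_0t == 0.0

    def test_negative_conc_rejected(self):
        with pytest.raises(ValueError):
            nca_metrics([0, 1, 2], [0, -1, 0])


class TestValidationMetrics:
    @pytest.mark.parametrize(
        "fe_expected, pe_expected",
        [(1.07, 0.07), (1.0, 0.0), (0.80, 0.20)],
    )
    def test_worked_examples(self, fe_expected, pe_expected):
        observed = 123.4
        predicted = fe_expected * observed
        v = validation_metrics(predicted, observed)
        assert v.fe == pytest.approx(fe_expected, abs=1e-12)
        assert v.pe == pytest.approx(pe_expected, abs=1e-12)

    def test_thresholds(self):
        assert validation_metrics(1.9, 1.0).pass_fe
        assert not validation_metrics(2.1, 1.0).pass_fe
        assert validation_metrics(1.19, 1.0).pass_pe
        assert not validation_metrics(1.21, 1.0).pass_pe

    @settings(max_examples=100, derandomize=True)
    @given(
        predicted=st.floats(1e-6, 1e6),
        observed=st.floats(1e-6, 1e6),
    )
    def test_pe_equals_abs_fe_minus_one(self, predicted, observed):
        assert prediction_error(predicted, observed) == pytest.approx(
            abs(fold_error(predicted, observed) - 1.0), rel=1e-9
        )

    def test_nonpositive_observed_rejected(self):
        with pytest.raises(ValueError):
            fold_error(1.0, 0.0)


class TestGMRRatio:
    @pytest.mark.parametrize(
        "t, r, expected",
        [
            (1263.52, 1215.67, 103.94),
            (55.32, 67.44, 82.03),
            (7.0, 7.0, 100.00),
        ],
    )
    def test_examples(self, t, r, expected):
        assert gmr_ratio_percent(t, r) == expected

    def test_positive_required(self):
        with pytest.raises(ValueError):
            gmr_ratio_percent(0.0, 1.0)


def _design_and_metrics(values: dict[int, tuple[str, float, float]]):
    """values: subject -> (sequence, value in T period, value in R period)."""
    drows, mrows = [], []
    for sid, (seq, vT, vR) in values.items():
        for period in (1, 2):
            trt = ("T" if period == 1 else "R") if seq == "TR" else (
                "R" if period == 1 else "T"
            )
            drows.append(
                {"subject_id": sid, "sequence": seq, "period": period,
                 "treatment": trt}
            )
            mrows.append(
                {"subject_id": sid, "period": period,
                 "cmax": vT if trt == "T" else vR,
                 "auc_0t": vT if trt == "T" else vR}
            )
    return pd.DataFrame(drows), pd.DataFrame(mrows)


def _ci_oracle(values):
    """Closed-form balanced 2x2 crossover oracle from within-subject
    log-differences: delta = mean of per-sequence means of u = log T - log R;
    SE from the pooled within-sequence variance of u."""
    u = {"TR": [], "RT": []}
    for seq, vT, vR in values.values():
        u[seq].append(math.log(vT) - math.log(vR))
    m = {k: np.mean(v) for k, v in u.items()}
    delta = (m["TR"] + m["RT"]) / 2
    n1, n2 = len(u["TR"]), len(u["RT"])
    ss = sum((x - m[k]) ** 2 for k in u for x in u[k])
    s2 = ss / (n1 + n2 - 2)
    se = math.sqrt(s2 / 4 * (1 / n1 + 1 / n2))
    tcrit = stats.t.ppf(0.95, n1 + n2 - 2)
    return (
        math.exp(delta) * 100,
        math.exp(delta - tcrit * se) * 100,
        math.exp(delta + tcrit * se) * 100,
    )


class TestCrossoverBE:
    VALUES = {
        1: ("TR", 105.0, 100.0),
        2: ("TR", 98.0, 104.0),
        3: ("TR", 111.0, 103.0),
        4: ("RT", 95.0, 99.0),
        5: ("RT", 102.0, 96.0),
        6: ("RT", 100.0, 101.0),
    }

    def test_matches_hand_oracle(self):
        design, metrics = _design_and_metrics(self.VALUES)
        res = be_crossover_analysis(design, metrics, "cmax")
        gmr, lo, hi = _ci_oracle(self.VALUES)
        assert res.gmr_pct == pytest.approx(gmr, abs=1e-10)
        assert res.ci90[0] == pytest.approx(lo, abs=1e-8)
        assert res.ci90[1] == pytest.approx(hi, abs=1e-8)

    def test_identical_t_and_r(self):
        vals = {i: (("TR" if i <= 3 else "RT"), 100.0 + i, 100.0 + i)
                for i in range(1, 7)}
        design, metrics = _design_and_metrics(vals)
        res = be_crossover_analysis(design, metrics, "auc_0t")
        assert res.gmr_pct == pytest.approx(100.0, abs=1e-9)
        assert res.passed

    def test_scale_invariance(self):
        design, metrics = _design_and_metrics(self.VALUES)
        scaled = metrics.copy()
        scaled[["cmax", "auc_0t"]] *= 37.5
        a = be_crossover_analysis(design, metrics, "cmax")
        b = be_crossover_analysis(design, scaled, "cmax")
        assert b.gmr_pct == pytest.approx(a.gmr_pct, rel=1e-12)
        assert b.ci90 == pytest.approx(a.ci90, rel=1e-12)

    def test_swap_reciprocal_symmetry(self):
        design, metrics = _design_and_metrics(self.VALUES)
        a = be_crossover_analysis(design, metrics, "cmax")
        swapped = design.copy()
        swapped["treatment"] = swapped["treatment"].map({"T": "R", "R": "T"})
        b = be_crossover_analysis(swapped, metrics, "cmax")
        assert b.gmr_pct == pytest.approx(1e4 / a.gmr_pct, rel=1e-10)
        assert b.ci90[0] == pytest.approx(1e4 / a.ci90[1], rel=1e-10)
        assert b.ci90[1] == pytest.approx(1e4 / a.ci90[0], rel=1e-10)

    def test_incomplete_subject_dropped_with_warning(self):
        design, metrics = _design_and_metrics(self.VALUES)
        extra_d = pd.DataFrame(
            [{"subject_id": 99, "sequence": "TR", "period": 1, "treatment": "T"}]
        )
        extra_m = pd.DataFrame(
            [{"subject_id": 99, "period": 1, "cmax": 100.0, "auc_0t": 100.0}]
        )
        with pytest.warns(UserWarning):
            res = be_crossover_analysis(
                pd.concat([design, extra_d], ignore_index=True),
                pd.concat([metrics, extra_m], ignore_index=True),
                "cmax",
            )
        assert res.n_subjects == 6

    def test_too_few_per_sequence(self):
        vals = {1: ("TR", 1.0, 1.1), 2: ("TR", 1.0, 1.1),
                3: ("RT", 1.0, 1.1), 4: ("RT", 1.0, 1.1)}
        design, metrics = _design_and_metrics(vals)
        with pytest.raises(ValueError):
            be_crossover_analysis(design, metrics, "cmax")
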