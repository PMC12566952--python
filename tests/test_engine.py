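"""ODE system assembly, integration identities, and disposition calibration."""

import numpy as np
import pytest

from fdcvbe import presets
from fdcvbe.absorption import GIPhysiology
from fdcvbe.dissolution import WeibullParams, weibull_fraction
from fdcvbe.engine import (
    CalibrationError,
    DispositionParams,
    assemble_odes,
    calibrate_disposition,
    simulate_subject,
)
from fdcvbe.pkstats import nca_metrics


class TestAssembly:
    def test_zero_dose_stays_zero(self, linear_drug, linear_disp, physiology):
        sys_ = assemble_odes(
            linear_drug, WeibullParams(td50=10, shape=1.2), physiology,
            linear_disp, dose_mg=0.0,
        )
        prof = simulate_subject(sys_, rtol=1e-8, atol=1e-10, n_out=97)
        assert np.all(prof.conc == 0.0)

    def test_missing_elimination_route_rejected(self, linear_drug, physiology):
        disp = DispositionParams(vc=10, vp=10, q=5)  # neither CL nor secretion
        with pytest.raises(ValueError):
            assemble_odes(
                linear_drug, WeibullParams(td50=10, shape=1.2), physiology,
                disp, dose_mg=100.0,
            )

    def test_rhs_conserves_mass_pointwise(self, glyburide_model, physiology):
        drug, form, disp, dose = glyburide_model
        sys_ = assemble_odes(drug, form, physiology, disp, dose)
        rng = np.random.default_rng(3)
        for _ in range(20):
            y = rng.uniform(0, sys_.dose_umol / 4, size=len(sys_.y0))
            t = float(rng.uniform(0, 2000))
            assert abs(float(np.sum(sys_.rhs(t, y)))) < 1e-10 * sys_.dose_umol

    def test_hazard_only_release_reproduces_weibull(self, linear_drug, linear_disp):
        """With the solubility cap slack and transit frozen, cumulative
        dissolution in the stomach equals the closed-form release curve."""
        drug = linear_drug.model_copy(deep=True)
        drug.ref_solubility = 1e8  # cap far from binding
        phys = GIPhysiology.default_fasted()
        phys.get_solid = phys.get_liquid = 1e9
        phys.sitt = phys.litt = 1e9
        form = WeibullParams(td50=9.7, shape=1.37)
        sys_ = assemble_odes(drug, form, phys, linear_disp, dose_mg=100.0)
        prof = simulate_subject(
            sys_, t_end_h=2.0, rtol=1e-10, atol=1e-12, n_out=121, keep_states=True
        )
        solid_total = prof.states[:6].sum(axis=0)
        released = 1.0 - solid_total / sys_.dose_umol
        expected = weibull_fraction(prof.times * 60.0, form)
        assert np.max(np.abs(released - expected)) < 1e-6


class TestIntegration:
    def test_iv_bolus_closed_form(self, linear_drug, physiology):
        """One-compartment i.v. bolus: AUC = D/CL, Cmax = D/Vc to 0.1%."""
        disp = DispositionParams(vc=10.0, vp=1.0, q=0.0, cl_hepatic=10.0)
        sys_ = assemble_odes(
            linear_drug, WeibullParams(td50=10, shape=1.2), physiology, disp,
            dose_mg=50.0, route="iv",
        )
        prof = simulate_subject(sys_, rtol=1e-10, atol=1e-12, n_out=2881)
        pk = nca_metrics(prof.times, prof.conc)
        d_umol = 50.0 * 1000 / linear_drug.mw
        auc_expected = d_umol / 10.0 * linear_drug.mw  # ng*h/mL
        cmax_expected = d_umol / 10.0 * linear_drug.mw
        assert pk.auc_0t == pytest.approx(auc_expected, rel=1e-3)
        assert pk.cmax == pytest.approx(cmax_expected, rel=1e-3)

    def test_mass_balance_closes(self, metformin_model, glyburide_model, physiology):
        for drug, form, disp, dose in (metformin_model, glyburide_model):
            sys_ = assemble_odes(drug, form, physiology, disp, dose)
            prof = simulate_subject(sys_, rtol=1e-6, atol=1e-8, n_out=145)
            assert prof.balance_error < 1e-6
            assert sum(prof.mass_balance_report.values()) == pytest.approx(1.0, abs=1e-6)
            assert prof.conc[0] == 0.0
            assert np.all(prof.conc >= 0.0)

    def test_dose_linearity_linear_regime(self, linear_drug, linear_disp, physiology):
        form = WeibullParams(td50=15.0, shape=1.3)
        aucs = []
        for dose in (50.0, 100.0):
            sys_ = assemble_odes(linear_drug, form, physiology, linear_disp, dose)
            prof = simulate_subject(sys_, rtol=1e-8, atol=1e-10, n_out=289)
            aucs.append(nca_metrics(prof.times, prof.conc).auc_0t)
        assert aucs[1] == pytest.approx(2 * aucs[0], rel=1e-3)

    def test_glyburide_cmax_monotone_in_td50(self, glyburide_model, physiology):
        """Slower release of the dissolution-limited component lowers its peak."""
        drug, _, disp, dose = glyburide_model
        cmaxes = []
        for td50 in (10.0, 77.22):
            sys_ = assemble_odes(
                drug, WeibullParams(td50=td50, shape=1.06), physiology, disp, dose
            )
            prof = simulate_subject(sys_, rtol=1e-6, atol=1e-8, n_out=289)
            cmaxes.append(nca_metrics(prof.times, prof.conc).cmax)
        assert cmaxes[0] > cmaxes[1]

    def test_supersaturation_controlled(self, glyburide_model, physiology):
        """Luminal concentrations track the segment solubility cap while
        solid remains to precipitate onto."""
        drug, form, disp, dose = glyburide_model
        sys_ = assemble_odes(drug, form, physiology, disp, dose)
        prof = simulate_subject(
            sys_, rtol=1e-8, atol=1e-10, n_out=577, keep_states=True
        )
        solid = prof.states[:6]
        conc = prof.states[6:12] / sys_.vol[:, None]
        cap = sys_.sol_umol[:, None]
        # wherever solid is present, dissolved conc may not exceed solubility
        # by more than a small solver overshoot
        present = solid > 1e-6 * sys_.dose_umol
        excess = (conc - cap)[present]
        assert excess.size == 0 or float(excess.max()) < 0.05 * cap.min()


class TestCalibration:
    def _targets(self, linear_drug, linear_disp, physiology, form):
        sys_ = assemble_odes(linear_drug, form, physiology, linear_disp, 100.0)
        prof = simulate_subject(sys_, rtol=1e-6, atol=1e-8, n_out=289)
        pk = nca_metrics(prof.times, prof.conc)
        return pk.cmax, pk.auc_0t

    def test_roundtrip_recovers_targets(self, linear_drug, linear_disp, physiology):
        """Two-stage random search reattains self-generated targets within 2%."""
        form = WeibullParams(td50=15.0, shape=1.3)
        cmax, auc = self._targets(linear_drug, linear_disp, physiology, form)
        space = {"vc": (15.0, 60.0), "cl_hepatic": (6.0, 24.0)}
        base = linear_disp
        r1 = calibrate_disposition(
            linear_drug, form, physiology, 100.0, cmax, auc,
            search_space=space, n_iter=80, seed=5, base=base,
        )
        narrowed = {
            "vc": (r1.disp.vc * 0.85, r1.disp.vc * 1.15),
            "cl_hepatic": (r1.disp.cl_hepatic * 0.85, r1.disp.cl_hepatic * 1.15),
        }
        r2 = calibrate_disposition(
            linear_drug, form, physiology, 100.0, cmax, auc,
            search_space=narrowed, n_iter=120, seed=6, base=base,
        )
        best = min(r1, r2, key=lambda r: r.loss)
        assert best.rel_err_cmax < 0.02
        assert best.rel_err_auc < 0.02

    def test_single_iteration_deterministic(self, linear_drug, linear_disp, physiology):
        form = WeibullParams(td50=15.0, shape=1.3)
        cmax, auc = self._targets(linear_drug, linear_disp, physiology, form)
        kwargs = dict(
            search_space={"vc": (20.0, 45.0), "cl_hepatic": (8.0, 18.0)},
            n_iter=1, seed=9, base=linear_disp,
        )

        def run_once():
            try:
                r = calibrate_disposition(
                    linear_drug, form, physiology, 100.0, cmax, auc, **kwargs
                )
            except CalibrationError as err:
                r = err.best
            return r

        a, b = run_once(), run_once()
        assert a is not None and b is not None
        assert a.disp.model_dump() == b.disp.model_dump()
        assert a.achieved_cmax == b.achieved_cmax

    def test_invalid_targets_rejected(self, linear_drug, physiology):
        with pytest.raises(ValueError):
            calibrate_disposition(
                linear_drug, WeibullParams(td50=15, shape=1.3), physiology,
                100.0, -1.0, 10.0, search_space={"vc": (1, 2)}, n_iter=1, seed=0,
            )
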