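"""Published parameter presets for the metformin-glyburide fixed-dose combination.

Physicochemical, ADME and formulation constants for the two active
ingredients of the 500 mg / 2.5 mg immediate-release combination tablet, as
reported for the reference (Glucovance) and test products, plus the
reference-arm exposure targets used to calibrate the reduced disposition
model and the default study configuration.

Two values are published for the specific renal tubular secretion rate of
metformin (85.42 and 68.42 umol/L/min); both ship as named presets with the
tabulated value as default.  The reduced two-compartment disposition
constants below were identified by this package's own Monte-Carlo
calibration (``analysis/02_calibrate_models.py``) against the reference-arm
geometric-mean Cmax and AUC0-t targets and are frozen here so downstream
analyses are reproducible without re-running the search.
"""

from __future__ import annotations

from .absorption import (
    DrugParameters,
    GIPhysiology,
    HepaticLinearElimination,
    RenalMMElimination,
    TransporterKinetics,
)
from .dissolution import WeibullParams
from .engine import DispositionParams

__all__ = [
    "TSMAX_SPEC_TABLE1",
    "TSMAX_SPEC_TEXT",
    "DOSE_MG",
    "REFERENCE_TARGETS",
    "metformin",
    "glyburide",
    "formulation",
    "default_physiology",
    "disposition_preset",
]

#: specific renal tubular secretion rate presets (umol/L/min)
TSMAX_SPEC_TABLE1 = 85.42
TSMAX_SPEC_TEXT = 68.42

#: label doses of the combination tablet (mg)
DOSE_MG = {"metformin": 500.0, "glyburide": 2.5}

#: reference-arm geometric means (Cmax ng/mL, AUC0-t ng*h/mL) used as
#: disposition calibration targets
REFERENCE_TARGETS = {
    "metformin": {"cmax": 1215.67, "auc_0t": 5770.53},
    "glyburide": {"cmax": 67.44, "auc_0t": 408.98},
}

#: Weibull release parameters: reference and test products
_FORMULATIONS = {
    ("metformin", "reference"): WeibullParams(td50=9.7, shape=1.37),
    ("metformin", "test"): WeibullParams(td50=10.0, shape=1.22),
    ("glyburide", "reference"): WeibullParams(td50=77.22, shape=1.06),
    ("glyburide", "test"): WeibullParams(td50=82.78, shape=1.10),
}

#: relative PMAT expression per GI segment (small intestine sums to 1;
#: colon at 0.1x small intestine; none in stomach/rectum)
_PMAT_EXPRESSION = {
    "stomach": 0.0,
    "duodenum": 0.25,
    "jejunum": 0.50,
    "ileum": 0.25,
    "colon": 0.10,
    "rectum": 0.0,
}


def metformin(tsmax_spec: float = TSMAX_SPEC_TABLE1) -> DrugParameters:
    """Metformin (BCS III): high solubility, carrier-mediated uptake,
    saturable renal tubular secretion."""
    return DrugParameters(
        name="metformin",
        mw=129.16,
        logp=-1.43,
        pka_list=[(2.8, "base"), (11.5, "base")],
        ref_solubility=350.9,
        ref_ph=6.8,
        peff_trans=5.80e-8,
        fu=1.0,
        transporter=TransporterKinetics(
            vmax=53.36,
            km=1320.0,
            hill_n=2.64,
            rel_expression=dict(_PMAT_EXPRESSION),
        ),
        elimination=RenalMMElimination(tsmax_spec=tsmax_spec, km=65.6),
    )


def glyburide() -> DrugParameters:
    """Glyburide (BCS II): pH-dependent low solubility (weak acid,
    pKa 5.3), high permeability, linear hepatic elimination, 1% unbound."""
    return DrugParameters(
        name="glyburide",
        mw=494.0,
        logp=3.75,
        pka_list=[(5.3, "acid")],
        ref_solubility=2.06e-3,
        ref_ph=8.31,
        peff_trans=6.27e-5,
        fu=0.01,
        transporter=None,
        elimination=HepaticLinearElimination(),
    )


def formulation(drug: str, product: str = "reference") -> WeibullParams:
    """Weibull release parameters of the reference or test product."""
    try:
        return _FORMULATIONS[(drug, product)].model_copy()
    except KeyError:
        raise KeyError(f"no formulation preset for ({drug!r}, {product!r})")


def default_physiology() -> GIPhysiology:
    return GIPhysiology.default_fasted()


# Frozen output of analysis/02_calibrate_models.py (Monte-Carlo search, seed
# recorded in results/calibration.json). capacity_scale applies to the PMAT
# transporter of metformin.
_DISPOSITION = {
    "metformin": {
        "disp": DispositionParams(
            vc=179.89450125602562,
            vp=179.48871012884396,
            q=21.219922400825247,
            secretion_scale=1.0903819479251016,
            gfr_filtration=True,
            gfr=0.12,
        ),
        "capacity_scale": 0.42825896144503933,
    },
    "glyburide": {
        "disp": DispositionParams(
            vc=1.0115636419878657,
            vp=1.135465526438518,
            q=5.24335688495898,
            cl_hepatic=456.730779295767,
            gfr_filtration=False,
        ),
        "capacity_scale": 1.0,
    },
}


def disposition_preset(drug: str) -> tuple[DispositionParams, float]:
    """Calibrated (disposition, transporter capacity_scale) for one drug."""
    entry = _DISPOSITION[drug]
    return entry["disp"].model_copy(deep=True), entry["capacity_scale"]


def drug_model(drug: str, product: str = "reference"):
    """Convenience: (DrugParameters with calibrated capacity, WeibullParams,
    DispositionParams, dose_mg) ready to simulate."""
    d = metformin() if drug == "metformin" else glyburide()
    disp, cap = disposition_preset(drug)
    if d.transporter is not None:
        d.transporter.capacity_scale = cap
    return d, formulation(drug, product), disp, DOSE_MG[drug]
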