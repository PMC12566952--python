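import numpy as np
import pytest

from fdcvbe import presets
from fdcvbe.absorption import (
    DrugParameters,
    GIPhysiology,
    HepaticLinearElimination,
)
from fdcvbe.engine import DispositionParams
from fdcvbe.population import PopulationSpec, assign_crossover, sample_population


@pytest.fixture(scope="session")
def physiology() -> GIPhysiology:
    return presets.default_physiology()


@pytest.fixture(scope="session")
def metformin_model():
    """(drug, reference form, disposition, dose) for metformin."""
    return presets.drug_model("metformin")


@pytest.fixture(scope="session")
def glyburide_model():
    return presets.drug_model("glyburide")


@pytest.fixture(scope="session")
def linear_drug() -> DrugParameters:
    """A high-solubility, passively absorbed, linearly cleared probe drug:
    every flux in its system is linear, so closed-form PK identities hold."""
    return DrugParameters(
        name="probe",
        mw=250.0,
        logp=1.0,
        pka_list=[],
        ref_solubility=100.0,
        ref_ph=7.0,
        peff_trans=1.0e-4,
        fu=1.0,
        transporter=None,
        elimination=HepaticLinearElimination(),
    )


@pytest.fixture(scope="session")
def linear_disp() -> DispositionParams:
    return DispositionParams(
        vc=30.0, vp=40.0, q=10.0, cl_hepatic=12.0, gfr_filtration=False
    )


@pytest.fixture(scope="session")
def small_population(physiology, glyburide_model):
    """12 subjects + crossover design shared by the population-level tests."""
    _, _, disp, _ = glyburide_model
    subjects = sample_population(PopulationSpec(n=12, seed=101), physiology, disp)
    design = assign_crossover(subjects, seed=202)
    return subjects, design
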