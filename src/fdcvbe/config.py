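"""Study configuration document: load/save the full drug/formulation/
physiology/disposition/population description as JSON or YAML."""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field

from .absorption import DrugParameters, GIPhysiology
from .dissolution import WeibullParams
from .engine import DispositionParams
from .population import PopulationSpec

__all__ = ["DrugBlock", "StudyConfig", "load_study_config", "save_study_config"]


class DrugBlock(BaseModel):
    drug: DrugParameters
    dose_mg: float = Field(gt=0)
    reference_form: WeibullParams
    test_form: WeibullParams
    disposition: DispositionParams


class StudyConfig(BaseModel):
    drugs: dict[str, DrugBlock]
    physiology: GIPhysiology
    population: PopulationSpec

    @classmethod
    def default(cls, n_subjects: int = 100, population_seed: int = 0) -> "StudyConfig":
        from . import presets

        blocks = {}
        for name in ("metformin", "glyburide"):
            d, ref, disp, dose = presets.drug_model(name, "reference")
            blocks[name] = DrugBlock(
                drug=d,
                dose_mg=dose,
                reference_form=ref,
                test_form=presets.formulation(name, "test"),
                disposition=disp,
            )
        return cls(
            drugs=blocks,
            physiology=GIPhysiology.default_fasted(),
            population=PopulationSpec(n=n_subjects, seed=population_seed),
        )


def load_study_config(path: str | Path) -> StudyConfig:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return StudyConfig.model_validate(data)


def save_study_config(cfg: StudyConfig, path: str | Path) -> None:
    path = Path(path)
    data = cfg.model_dump(mode="json")
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))
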