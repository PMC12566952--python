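"""Synthetic-data generators: dissolution profiles, observed PK datasets,
and a one-command demo study bundle.

The real clinical concentration data are confidential, so every pipeline
input can be emulated: noisy Weibull-shaped dissolution profiles on the
in vitro sampling schedules, and "observed" concentration-time datasets on
the 22-point clinical schedule with a conventional proportional + additive
residual-error model.  All generators are bit-reproducible under a fixed
seed, and their zero-noise limits are exact inverses of the corresponding
fitters/estimators.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .dissolution import DissolutionProfile, WeibullParams, weibull_fraction
from .engine import CLINICAL_TIMES_H, ConcentrationProfile

__all__ = [
    "NoiseModel",
    "SCHEDULES_MIN",
    "synth_dissolution",
    "synth_observed_pk",
    "make_demo_study",
]

#: in vitro sampling schedules (minutes)
SCHEDULES_MIN = {
    "metformin_2_3": (5.0, 10.0, 15.0, 30.0, 45.0, 60.0),
    "glyburide_2_3": (5.0, 10.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0, 180.0, 240.0),
}

DEFAULT_MEDIA_PH = (1.2, 4.5, 6.8)


class NoiseModel(BaseModel):
    dissolution_sd: float = Field(default=2.0, ge=0, description="percent points")
    pk_proportional_cv: float = Field(default=0.10, ge=0)
    pk_additive_sd: float = Field(default=0.5, ge=0, description="ng/mL")
    seed: int = 0


def synth_dissolution(
    p: WeibullParams,
    schedule: str | tuple[float, ...] = "metformin_2_3",
    noise: NoiseModel | None = None,
    media_ph: tuple[float, ...] = DEFAULT_MEDIA_PH,
    label: str = "synthetic",
) -> list[DissolutionProfile]:
    """Noisy Weibull dissolution profiles, one per medium.

    Percent dissolved = 100*F(t) + N(0, sd), clipped to [0, 105].
    """
    noise = noise or NoiseModel()
    times = np.asarray(
        SCHEDULES_MIN[schedule] if isinstance(schedule, str) else schedule, float
    )
    rng = np.random.default_rng(noise.seed)
    profiles = []
    for ph in media_ph:
        pct = 100.0 * weibull_fraction(times, p)
        if noise.dissolution_sd > 0:
            pct = pct + rng.normal(0.0, noise.dissolution_sd, size=times.size)
        pct = np.clip(pct, 0.0, 105.0)
        profiles.append(
            DissolutionProfile(
                times=times.tolist(),
                pct_dissolved=pct.tolist(),
                medium_ph=ph,
                label=f"{label}_pH{ph}",
            )
        )
    return profiles


def synth_observed_pk(
    true_profile: ConcentrationProfile,
    noise: NoiseModel | None = None,
    n_subjects: int = 1,
) -> pd.DataFrame:
    """Observed dataset at the 22-point clinical schedule.

    conc_obs = conc*(1 + proportional) + additive, floored at 0; one block of
    22 rows per subject.  Requires the true profile to cover 0-48 h.
    """
    noise = noise or NoiseModel()
    if true_profile.times[-1] < CLINICAL_TIMES_H[-1]:
        raise ValueError("true profile must cover the 0-48 h window")
    rng = np.random.default_rng(noise.seed)
    base = np.interp(CLINICAL_TIMES_H, true_profile.times, true_profile.conc)
    frames = []
    for sid in range(1, n_subjects + 1):
        conc = base.copy()
        if noise.pk_proportional_cv > 0:
            conc = conc * (1.0 + rng.normal(0, noise.pk_proportional_cv, conc.size))
        if noise.pk_additive_sd > 0:
            conc = conc + rng.normal(0, noise.pk_additive_sd, conc.size)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "time_h": CLINICAL_TIMES_H,
                    "conc_ng_ml": np.maximum(conc, 0.0),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_demo_study(seed: int, out_dir: str | Path) -> dict:
    """Write a self-contained demo bundle and return its manifest.

    Contents: the study configuration (drug/formulation/physiology/
    disposition/population document), synthetic dissolution CSVs for both
    products of both components, synthetic observed PK CSVs, and a manifest
    with a checksum per artifact.  Same seed -> identical checksums.
    """
    from . import presets
    from .config import StudyConfig, save_study_config
    from .engine import assemble_odes, simulate_subject

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "files": {}}

    cfg = StudyConfig.default(population_seed=seed)
    cfg_path = out / "study.json"
    save_study_config(cfg, cfg_path)

    rng = np.random.default_rng(seed)
    for drug in ("metformin", "glyburide"):
        schedule = f"{drug}_2_3"
        for product in ("reference", "test"):
            form = presets.formulation(drug, product)
            profiles = synth_dissolution(
                form,
                schedule,
                NoiseModel(seed=int(rng.integers(2**31 - 1))),
                label=f"{drug}_{product}",
            )
            rows = []
            for prof in profiles:
                for t, y in zip(prof.times, prof.pct_dissolved):
                    rows.append(
                        {
                            "time_min": t,
                            "pct_dissolved": y,
                            "medium_pH": prof.medium_ph,
                            "label": prof.label,
                        }
                    )
            pd.DataFrame(rows).to_csv(
                out / f"dissolution_{drug}_{product}.csv", index=False
            )

        d, form, disp, dose = presets.drug_model(drug, "reference")
        prof = simulate_subject(
            assemble_odes(d, form, presets.default_physiology(), disp, dose),
            rtol=1e-6, atol=1e-8,
        )
        obs = synth_observed_pk(
            prof,
            NoiseModel(
                seed=int(rng.integers(2**31 - 1)),
                pk_additive_sd=5.0 if drug == "metformin" else 0.5,
            ),
            n_subjects=6,
        )
        obs.insert(1, "period", 1)
        obs.insert(2, "treatment", "R")
        obs.to_csv(out / f"observed_{drug}.csv", index=False)

    for path in sorted(out.glob("*")):
        if path.name != "manifest.json":
            manifest["files"][path.name] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
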