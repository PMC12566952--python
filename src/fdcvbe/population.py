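"""Virtual population sampling and 2x2 crossover design construction.

Each virtual subject carries two independently sampled GI physiology states
(the within-subject variability of the trial: period 1 is simulated under
``gi_state_1``, period 2 under ``gi_state_2``) and a single disposition
parameter set held constant across periods, so formulation differences are
expressed only through the absorption environment.  Subjects are randomly
split into balanced TR/RT sequences, each sequence further stratified into
two GI-condition subgroups (GI1/GI2) as design metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .absorption import SEGMENTS, GIPhysiology
from .engine import DispositionParams

__all__ = [
    "PopulationSpec",
    "VirtualSubject",
    "CrossoverDesign",
    "default_gi_ranges",
    "sample_population",
    "assign_crossover",
]

_PH_KEYS = tuple(f"{s}_ph" for s in SEGMENTS)
_TIME_KEYS = ("get_liquid", "get_solid", "sitt", "litt")


def default_gi_ranges() -> dict[str, tuple[float, float]]:
    """Default fasted GI sampling ranges (uniform low/high), configurable."""
    return {
        "stomach_ph": (1.3, 2.5),
        "duodenum_ph": (5.8, 6.5),
        "jejunum_ph": (6.0, 7.0),
        "ileum_ph": (6.8, 7.5),
        "colon_ph": (5.5, 7.0),
        "rectum_ph": (6.5, 7.5),
        "get_liquid": (10.0, 30.0),  # min
        "get_solid": (15.0, 60.0),  # min
        "sitt": (120.0, 300.0),  # min (2-5 h)
        "litt": (600.0, 2400.0),  # min (10-40 h)
    }


class PopulationSpec(BaseModel):
    """Specification of the virtual trial population."""

    n: int = Field(ge=2)
    parameter_ranges: dict[str, tuple[float, float]] = Field(
        default_factory=default_gi_ranges
    )
    age_range: tuple[float, float] = (18.0, 60.0)
    bmi_range: tuple[float, float] = (19.0, 27.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PopulationSpec":
        if self.n % 2 != 0:
            raise ValueError("n must be even for sequence balance")
        for key, (lo, hi) in self.parameter_ranges.items():
            if key not in _PH_KEYS + _TIME_KEYS:
                raise ValueError(f"unknown GI parameter {key!r}")
            if not lo < hi:
                raise ValueError(f"empty range for {key}: ({lo}, {hi})")
        for lo, hi in (self.age_range, self.bmi_range):
            if not lo < hi:
                raise ValueError("empty demographic range")
        return self


@dataclass
class VirtualSubject:
    id: int
    age: float
    bmi: float
    gi_state_1: GIPhysiology
    gi_state_2: GIPhysiology
    disposition: DispositionParams


def _sample_gi_state(
    rng: np.random.Generator,
    base: GIPhysiology,
    ranges: dict[str, tuple[float, float]],
) -> GIPhysiology:
    phys = base.model_copy(deep=True)
    for key, (lo, hi) in ranges.items():
        val = float(rng.uniform(lo, hi))
        if key.endswith("_ph"):
            phys.segment_ph[key[: -len("_ph")]] = val
        else:
            setattr(phys, key, val)
    return phys


def sample_population(
    spec: PopulationSpec,
    base_phys: GIPhysiology,
    disposition: DispositionParams,
) -> list[VirtualSubject]:
    """Draw ``spec.n`` virtual subjects, bit-reproducible for a fixed seed.

    Every GI parameter is drawn uniformly within its range; a subject's two
    GI states are independent draws.  Demographics are recorded metadata.
    The (population-level) disposition is shared by all subjects and held
    constant across periods.
    """
    rng = np.random.default_rng(spec.seed)
    subjects = []
    for i in range(spec.n):
        age = float(rng.uniform(*spec.age_range))
        bmi = float(rng.uniform(*spec.bmi_range))
        g1 = _sample_gi_state(rng, base_phys, spec.parameter_ranges)
        g2 = _sample_gi_state(rng, base_phys, spec.parameter_ranges)
        subjects.append(
            VirtualSubject(
                id=i + 1,
                age=age,
                bmi=bmi,
                gi_state_1=g1,
                gi_state_2=g2,
                disposition=disposition.model_copy(deep=True),
            )
        )
    return subjects


@dataclass
class CrossoverDesign:
    """2x2 crossover design table.

    ``table`` has one row per subject-period:
    subject_id, sequence (TR/RT), subgroup (GI1/GI2), period (1/2),
    treatment (T/R), gi_state (1/2).
    """

    sequence: dict[int, str]
    subgroup: dict[int, str]
    table: pd.DataFrame

    def rows(self) -> pd.DataFrame:
        return self.table


def assign_crossover(subjects: list[VirtualSubject], seed: int = 0) -> CrossoverDesign:
    """Randomly assign subjects to balanced TR/RT sequences.

    Period 1 always uses ``gi_state_1`` and period 2 ``gi_state_2``; within
    each sequence the first half (in randomised order) is tagged GI1 and the
    second GI2.  Raises for an odd subject count.
    """
    n = len(subjects)
    if n % 2 != 0:
        raise ValueError("crossover assignment needs an even subject count")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    ids = [subjects[i].id for i in order]
    half = n // 2
    sequence = {sid: ("TR" if k < half else "RT") for k, sid in enumerate(ids)}
    subgroup = {}
    for seq_ids in (ids[:half], ids[half:]):
        for k, sid in enumerate(seq_ids):
            subgroup[sid] = "GI1" if k < len(seq_ids) // 2 else "GI2"

    rows = []
    for s in subjects:
        seq = sequence[s.id]
        for period in (1, 2):
            if seq == "TR":
                treatment = "T" if period == 1 else "R"
            else:
                treatment = "R" if period == 1 else "T"
            rows.append(
                {
                    "subject_id": s.id,
                    "sequence": seq,
                    "subgroup": subgroup[s.id],
                    "period": period,
                    "treatment": treatment,
                    "gi_state": period,
                }
            )
    table = pd.DataFrame(rows)
    return CrossoverDesign(sequence=sequence, subgroup=subgroup, table=table)
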