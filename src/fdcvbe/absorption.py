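"""GI segment physiology, pH-dependent solubility, and luminal flux laws.

The gastrointestinal tract is represented as six well-stirred compartments in
series (stomach, duodenum, jejunum, ileum, colon, rectum), each carrying a pH,
a luminal fluid volume, an effective absorptive surface area, and first-order
transit rates.  Dissolved and undisintegrated (solid) drug transit separately
out of the stomach — liquid at 1/GET_liquid, solid at 1/GET_solid — and
together thereafter.  The small-intestinal transit time is split
duodenum:jejunum:ileum = 10:45:45 and the large-intestinal time
colon:rectum = 80:20.

Solubility follows Henderson-Hasselbalch scaling anchored at a reference
(pH, solubility) pair: for a monoprotic weak acid

    S(pH) = S0 * (1 + 10**(pH - pKa)),

with bases mirrored, multiple ionisable groups contributing additively, and
S0 solved from the anchor.  Absorptive flux out of a segment is the sum of a
linear sink-condition transcellular term, ``peff * SA * C / 1000`` (cm/min *
cm^2 * umol/L / (cm^3/L) = umol/min), and, where a carrier is expressed, a
Hill-saturable transporter term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

SEGMENTS = ("stomach", "duodenum", "jejunum", "ileum", "colon", "rectum")
SITT_SPLIT = {"duodenum": 0.10, "jejunum": 0.45, "ileum": 0.45}
LITT_SPLIT = {"colon": 0.80, "rectum": 0.20}

__all__ = [
    "SEGMENTS",
    "TransporterKinetics",
    "RenalMMElimination",
    "HepaticLinearElimination",
    "DrugParameters",
    "GIPhysiology",
    "GISegment",
    "solubility_at_ph",
    "carrier_flux",
    "passive_flux",
    "build_gi_segments",
]


class TransporterKinetics(BaseModel):
    """Saturable (Hill) intestinal uptake carrier.

    ``vmax`` is kept in the source's specific unit and bridged to an absolute
    amount rate (umol/min) by the dimensionless ``capacity_scale``, which is
    a calibrated constant of the reduced model.  ``rel_expression`` holds the
    per-segment relative expression multipliers (small-intestinal entries
    conventionally summing to 1).
    """

    vmax: float = Field(ge=0)
    km: float = Field(gt=0, description="umol/L")
    hill_n: float = Field(gt=0)
    rel_expression: dict[str, float]
    capacity_scale: float = Field(default=1.0, ge=0)

    @field_validator("rel_expression")
    @classmethod
    def _nonneg(cls, v: dict[str, float]) -> dict[str, float]:
        for seg, x in v.items():
            if seg not in SEGMENTS:
                raise ValueError(f"unknown segment {seg!r}")
            if x < 0:
                raise ValueError("rel_expression must be >= 0")
        return v


class RenalMMElimination(BaseModel):
    """Saturable renal tubular secretion (Michaelis-Menten on unbound conc)."""

    kind: Literal["renal_mm"] = "renal_mm"
    tsmax_spec: float = Field(gt=0, description="umol/L/min (specific rate)")
    km: float = Field(gt=0, description="umol/L")


class HepaticLinearElimination(BaseModel):
    """Linear hepatic clearance acting on unbound plasma concentration."""

    kind: Literal["hepatic_linear"] = "hepatic_linear"


class DrugParameters(BaseModel):
    """Physicochemical and ADME constants for one active ingredient."""

    name: str
    mw: float = Field(gt=0, description="g/mol")
    logp: float
    pka_list: list[tuple[float, Literal["acid", "base"]]] = Field(default_factory=list)
    ref_solubility: float = Field(gt=0, description="g/L at ref_ph")
    ref_ph: float
    peff_trans: float = Field(ge=0, description="cm/min")
    fu: float = Field(gt=0, le=1.0)
    transporter: Optional[TransporterKinetics] = None
    elimination: RenalMMElimination | HepaticLinearElimination

    def solubility_umol(self, ph: float) -> float:
        """Solubility in umol/L at the given pH."""
        return solubility_at_ph(self, ph) / self.mw * 1e6


class GIPhysiology(BaseModel):
    """Per-segment pH, volumes, areas, and transit times for one GI state."""

    segment_ph: dict[str, float]
    get_liquid: float = Field(gt=0, description="min, gastric emptying (dissolved)")
    get_solid: float = Field(gt=0, description="min, gastric emptying (solid)")
    sitt: float = Field(gt=0, description="min, small-intestinal transit")
    litt: float = Field(gt=0, description="min, large-intestinal transit")
    segment_volumes: dict[str, float]
    segment_surface_area: dict[str, float]

    @model_validator(mode="after")
    def _check(self) -> "GIPhysiology":
        for m, name in (
            (self.segment_ph, "segment_ph"),
            (self.segment_volumes, "segment_volumes"),
            (self.segment_surface_area, "segment_surface_area"),
        ):
            missing = set(SEGMENTS) - set(m)
            if missing:
                raise ValueError(f"{name} missing segments {sorted(missing)}")
        for seg, ph in self.segment_ph.items():
            if not 1.0 <= ph <= 9.0:
                raise ValueError(f"{seg} pH {ph} outside [1, 9]")
        for seg, v in self.segment_volumes.items():
            if v <= 0:
                raise ValueError("segment volumes must be > 0")
        for seg, a in self.segment_surface_area.items():
            if a < 0:
                raise ValueError("surface areas must be >= 0")
        return self

    @classmethod
    def default_fasted(cls) -> "GIPhysiology":
        """Typical fasted adult defaults (configurable; effective absorptive
        surface areas include villous/microvillous amplification)."""
        return cls(
            segment_ph={
                "stomach": 1.8,
                "duodenum": 6.0,
                "jejunum": 6.5,
                "ileum": 7.0,
                "colon": 6.5,
                "rectum": 6.8,
            },
            get_liquid=15.0,
            get_solid=30.0,
            sitt=210.0,
            litt=1320.0,
            segment_volumes={
                "stomach": 0.05,
                "duodenum": 0.03,
                "jejunum": 0.10,
                "ileum": 0.10,
                "colon": 0.05,
                "rectum": 0.01,
            },
            segment_surface_area={
                "stomach": 5.0e2,
                "duodenum": 2.0e5,
                "jejunum": 1.2e6,
                "ileum": 8.0e5,
                "colon": 3.0e5,
                "rectum": 1.0e3,
            },
        )


@dataclass
class GISegment:
    """One compartment of the assembled transit chain."""

    name: str
    ph: float
    volume: float
    surface_area: float
    residence: float  # min (solid residence for stomach)
    k_solid: float  # 1/min
    k_dissolved: float  # 1/min
    absorption_enabled: bool


def solubility_at_ph(drug: DrugParameters, ph: float) -> float:
    """Henderson-Hasselbalch solubility (g/L) at a pH in [0, 14].

    Ionisation factor f(pH) = 1 + sum_acids 10^(pH-pKa) + sum_bases
    10^(pKa-pH); the intrinsic solubility S0 is solved from the reference
    anchor, so S(ref_ph) = ref_solubility by construction.  A drug with no
    pKa entries has constant solubility.
    """
    if not 0.0 <= ph <= 14.0:
        raise ValueError(f"pH {ph} outside [0, 14]")

    def factor(p: float) -> float:
        f = 1.0
        for pka, kind in drug.pka_list:
            f += 10.0 ** (p - pka) if kind == "acid" else 10.0 ** (pka - p)
        return f

    s0 = drug.ref_solubility / factor(drug.ref_ph)
    return s0 * factor(ph)


def carrier_flux(
    k: TransporterKinetics, c_lumen: float, segment: str
) -> float:
    """Saturable carrier-mediated absorption rate (umol/min) in a segment.

    rate = Vmax_eff * C^n / (Km^n + C^n) with
    Vmax_eff = vmax * rel_expression[segment] * capacity_scale.
    """
    if c_lumen < 0:
        raise ValueError("negative luminal concentration")
    vmax_eff = k.vmax * k.rel_expression.get(segment, 0.0) * k.capacity_scale
    if c_lumen == 0.0 or vmax_eff == 0.0:
        return 0.0
    cn = c_lumen**k.hill_n
    return vmax_eff * cn / (k.km**k.hill_n + cn)


def passive_flux(peff: float, sa: float, c_lumen: float) -> float:
    """Linear sink-condition transcellular flux (umol/min)."""
    if peff < 0 or sa < 0 or c_lumen < 0:
        raise ValueError("passive_flux arguments must be >= 0")
    return peff * sa * c_lumen / 1000.0


def build_gi_segments(
    phys: GIPhysiology, stomach_absorption: bool = False
) -> list[GISegment]:
    """Assemble the six-segment transit chain with first-order rates.

    Stomach empties dissolved drug at 1/get_liquid and solid at 1/get_solid;
    intestinal residence times follow the fixed SITT/LITT splits.  Stomach
    absorption is disabled by default (negligible for both components).
    """
    residences = {
        "stomach": phys.get_solid,
        **{s: f * phys.sitt for s, f in SITT_SPLIT.items()},
        **{s: f * phys.litt for s, f in LITT_SPLIT.items()},
    }
    segs = []
    for name in SEGMENTS:
        tau = residences[name]
        k_sol = 1.0 / (phys.get_solid if name == "stomach" else tau)
        k_dis = 1.0 / (phys.get_liquid if name == "stomach" else tau)
        segs.append(
            GISegment(
                name=name,
                ph=phys.segment_ph[name],
                volume=phys.segment_volumes[name],
                surface_area=phys.segment_surface_area[name],
                residence=tau,
                k_solid=k_sol,
                k_dissolved=k_dis,
                absorption_enabled=(name != "stomach") or stomach_absorption,
            )
        )
    return segs
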