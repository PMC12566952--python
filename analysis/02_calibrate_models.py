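"""Identify the reduced two-compartment disposition parameters of each
component by staged Monte-Carlo random search against the reference-arm
geometric-mean exposure targets (Cmax, AUC0-t).

The winning constants are frozen in fdcvbe.presets so the rest of the
pipeline does not depend on re-running this search; this script reproduces
them deterministically and writes results/calibration.json.
"""

import json
from pathlib import Path

from fdcvbe import presets
from fdcvbe.engine import DispositionParams, calibrate_disposition
from fdcvbe.presets import REFERENCE_TARGETS

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)

# staged search: coarse global stage(s), then a narrowed stage around the
# incumbent; seeds fixed for reproducibility
MET_STAGES = [
    (
        {"vc": (20, 200), "vp": (50, 500), "q": (10, 60),
         "secretion_scale": (0.05, 20), "capacity_scale": (0.02, 5)},
        400, 20260930,
    ),
    (
        {"vc": (120, 220), "vp": (80, 200), "q": (15, 45),
         "secretion_scale": (0.5, 3.0), "capacity_scale": (0.2, 1.2)},
        400, 20260931,
    ),
]
GLY_STAGES = [
    ({"vc": (3, 40), "vp": (3, 80), "q": (1, 30), "cl_hepatic": (50, 2000)},
     400, 20260932),
    ({"vc": (2, 15), "vp": (2, 40), "q": (0.5, 15), "cl_hepatic": (250, 1200)},
     600, 20260933),
    ({"vc": (0.8, 5), "vp": (1.0, 10), "q": (1, 12), "cl_hepatic": (380, 800)},
     600, 20260934),
]


def run(drug_name: str, stages, base: DispositionParams) -> dict:
    phys = presets.default_physiology()
    drug = presets.metformin() if drug_name == "metformin" else presets.glyburide()
    form = presets.formulation(drug_name, "reference")
    dose = presets.DOSE_MG[drug_name]
    targets = REFERENCE_TARGETS[drug_name]
    best = None
    for space, n_iter, seed in stages:
        r = calibrate_disposition(
            drug, form, phys, dose, targets["cmax"], targets["auc_0t"],
            search_space=space, n_iter=n_iter, seed=seed, base=base,
        )
        if best is None or r.loss < best.loss:
            best = r
    return {
        "disposition": best.disp.model_dump(),
        "capacity_scale": best.capacity_scale,
        "achieved_cmax": best.achieved_cmax,
        "achieved_auc_0t": best.achieved_auc,
        "rel_err_cmax": best.rel_err_cmax,
        "rel_err_auc": best.rel_err_auc,
        "target_cmax": targets["cmax"],
        "target_auc_0t": targets["auc_0t"],
        "stages": [{"n_iter": n, "seed": s} for _, n, s in stages],
    }


def main() -> None:
    out = {
        "metformin": run(
            "metformin", MET_STAGES,
            DispositionParams(vc=100, vp=100, q=20, secretion_scale=1.0),
        ),
        "glyburide": run(
            "glyburide", GLY_STAGES,
            DispositionParams(vc=10, vp=10, q=5, cl_hepatic=300,
                              gfr_filtration=False),
        ),
    }
    (RESULTS / "calibration.json").write_text(json.dumps(out, indent=2))
    for drug, res in out.items():
        print(
            f"{drug}: Cmax {res['achieved_cmax']:.2f} "
            f"(target {res['target_cmax']}, err {100*res['rel_err_cmax']:.1f}%), "
            f"AUC {res['achieved_auc_0t']:.1f} "
            f"(target {res['target_auc_0t']}, err {100*res['rel_err_auc']:.1f}%)"
        )
        frozen, cap = presets.disposition_preset(drug)
        match = frozen.model_dump() == res["disposition"] and cap == res["capacity_scale"]
        print(f"  matches frozen preset: {match}")


if __name__ == "__main__":
    main()
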