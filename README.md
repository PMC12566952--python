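# fdcvbe

Physiologically based biopharmaceutics modeling (PBBM), virtual
bioequivalence, and dissolution safe-space analysis for a metformin
(500 mg) / glyburide (2.5 mg) fixed-dose-combination (FDC) tablet.

## The problem

A generic FDC must demonstrate bioequivalence (BE) for *every* active
ingredient — the combination fails if one component fails.  The two
components here are biopharmaceutical opposites: metformin is highly
soluble but poorly permeable (BCS III, carrier-mediated uptake, saturable
renal tubular secretion), while glyburide is poorly soluble but highly
permeable (BCS II, weak acid with strongly pH-dependent dissolution,
hepatic clearance, 99% protein bound).  A mechanistic oral-absorption model
lets formulation attributes (the in vitro release curve) be propagated to
in vivo exposure, so that the *dissolution safe space* — the range of
release behaviours that still yields BE — can be mapped by simulation
instead of by repeated clinical trials.

This package is aimed at biopharmaceutics modelers: it provides the
building blocks (Weibull release kinetics, a six-segment GI transit and
absorption ODE model, a reduced two-compartment disposition, virtual
populations with within-subject GI variability, crossover TOST statistics)
and the assembled analyses (`analysis/01`–`06`).

## The model in brief

* Release: Weibull, `F(t) = 1 − exp(−ln2·((t−T_lag)/td50)^b)`,
  parameterised by the 50%-dissolution time `td50`; the ODE engine uses its
  hazard form as a time-varying first-order rate on the solid pool.
* Absorption: six GI segments in series with first-order transit (separate
  gastric emptying of solid and liquid), Henderson–Hasselbalch pH-dependent
  solubility with a supersaturation/precipitation cap, linear transcellular
  flux plus a Hill-saturable uptake carrier for metformin.
* Disposition: reduced two-compartment model with Michaelis–Menten renal
  secretion (metformin) or linear hepatic clearance on unbound drug
  (glyburide), calibrated by Monte-Carlo search to the reference-arm
  geometric means.
* Statistics: NCA (Cmax, Tmax, trapezoidal AUC0–t), FE/PE validation
  metrics, and the fixed-effects 2×2 crossover TOST with 80.00–125.00%
  bounds on the 90% CI of the geometric mean ratio (GMR).

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

Virtual bioequivalence of the test vs reference products in a 100-subject
2×2 crossover (`python analysis/05_vbe.py`) prints:

```
metformin:
  cmax    GMR 100.15%  90% CI  99.34-100.96%  PASS
  auc_0t  GMR 100.14%  90% CI  99.81-100.47%  PASS
glyburide:
  cmax    GMR  98.30%  90% CI  94.07-102.73%  PASS
  auc_0t  GMR 100.25%  90% CI  96.74-103.89%  PASS

Fixed-dose-combination verdict (all four tests): BIOEQUIVALENT
```

Each line is one TOST: the geometric mean ratio of the test to reference
exposure metric with its 90% confidence interval; a metric passes when the
whole interval lies inside 80.00–125.00%.  Metformin's interval is tight
because its exposure depends mainly on transit times (low within-subject
variability); glyburide's is wider because its dissolution — hence exposure
— responds steeply to the sampled small-intestinal pH.  The combination
verdict requires all four tests to pass.

The same population then drives the safe-space scan
(`python analysis/06_safe_space.py`), which varies the test batches'
50%-dissolution time, re-runs the crossover TOST at every grid point
(bisecting each pass/fail transition to 1 min), and reports the
BE-preserving window per component; `results/safe_space_<drug>.csv` holds
the full per-batch GMR/CI table.

A minimal library-level session:

```python
from fdcvbe import presets, assemble_odes, simulate_subject, nca_metrics

drug, form, disp, dose = presets.drug_model("glyburide")
profile = simulate_subject(
    assemble_odes(drug, form, presets.default_physiology(), disp, dose)
)
print(nca_metrics(profile.times, profile.conc))
# PKMetrics(cmax=67.33, tmax=2.67, auc_0t=426.4)   (ng/mL, h, ng*h/mL)
```

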