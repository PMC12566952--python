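# Methods

`fdcvbe` implements a reduced physiologically based biopharmaceutics model
(PBBM) for an immediate-release metformin (500 mg) / glyburide (2.5 mg)
fixed-dose-combination tablet, and the population-level analyses built on it:
local sensitivity screening, virtual bioequivalence (VBE) in a 2×2 crossover,
and exploration of the dissolution "safe space" — the range of release
behaviours within which a batch remains bioequivalent to the reference
product.

## Release model

Tablet release is empirical Weibull kinetics,

    F(t) = 1 − exp(−ln 2 · ((t − T_lag)/td50)^b),

parameterised by the 50%-dissolution time `td50` (min), the shape `b`, and an
optional lag.  The conventional scale parameter is `a = td50^b / ln 2`; using
`td50` directly makes published "50% dissolved time" values usable verbatim
and makes `F(T_lag + td50) = 0.5` hold exactly for every shape.  The ODE
engine consumes the hazard form `h(t) = f/(1−F) = ln 2 · b/td50 ·
((t−T_lag)/td50)^(b−1)`, applied as a first-order rate on the undissolved
pool; integrating the hazard reproduces `F` exactly when the solubility cap
is slack (verified to 1e−6 in the tests).  Weibull fitting is bounded
nonlinear least squares with multi-start (td50 started at the observation
nearest 50% dissolved; shape at {0.7, 1, 2}); `T_lag` is held at 0 unless
explicitly freed.  Profile similarity uses the regulatory f2 statistic with
the standard subsetting (at most one point retained after both profiles
exceed 85%).

## Absorption model

The GI tract is six well-stirred compartments in series (stomach, duodenum,
jejunum, ileum, colon, rectum) with first-order transit.  Dissolved drug
leaves the stomach at `1/GET_liquid` and undisintegrated solid at
`1/GET_solid`; the small-intestinal transit time is split
duodenum:jejunum:ileum = 10:45:45 and the colonic time colon:rectum = 80:20.
These splits and the default fasted state (pH 1.8/6.0/6.5/7.0/6.5/6.8;
volumes 0.05/0.03/0.10/0.10/0.05/0.01 L; liquid GET 15 min, solid GET 30 min,
SITT 3.5 h, LITT 22 h) are typical-adult values and are fully configurable.
Segment surface areas are *effective absorptive* areas, i.e. they fold in
villous/microvillous amplification (duodenum 2×10⁵, jejunum 1.2×10⁶, ileum
8×10⁵, colon 3×10⁵ cm²); the transcellular permeability coefficients they
multiply are small-number constants of the source parameterisation, and only
the product `P_eff · SA` is identifiable in a lumped model.

Solubility follows Henderson–Hasselbalch scaling anchored at a reference
(pH, solubility) pair; multiple ionisable groups contribute additively to
the ionisation factor.  For glyburide (weak acid, pKa 5.3, anchor
2.06×10⁻³ g/L at pH 8.31) this gives an intrinsic solubility of ~2×10⁻⁶ g/L
and a steep rise across small-intestinal pH — the mechanistic source of its
pH sensitivity.  Dissolution flux in each segment is
`h(t)·solid·(1 − C/S(pH))`: the bracket caps dissolution at the local
solubility and becomes negative (precipitation onto the residual solid pool)
under supersaturation.  Precipitation therefore requires solid to nucleate
on; a segment that receives supersaturated fluid after its solid is
exhausted retains the excess in solution.

Absorption per segment is the sum of a linear sink-condition transcellular
term `P_eff·SA·C/1000` and, for metformin, a Hill-saturable carrier
(PMAT: Km 1320 µmol/L, Hill n 2.64, relative expression
duodenum/jejunum/ileum = 0.25/0.50/0.25, colon at 0.1× the small intestine,
none in stomach or rectum).  Stomach absorption is disabled by default for
both components.  The carrier's published capacity constant is in a
simulator-specific unit, so it is bridged to an absolute amount rate by one
dimensionless calibrated `capacity_scale`.

## Disposition and calibration

Systemic disposition is a deliberately reduced two-compartment model, not
the original whole-body PBPK: the whole-body tissue-partition machinery is
not reproducible from the published parameters, and none of the questions
under study (release, transit, transporters, elimination route) depend on
it.  Elimination acts on the unbound concentration `C_u = fu·C`:

* metformin — saturable renal tubular secretion
  `secretion_scale · TS_max_spec · C_u/(Km + C_u)` (TS_max_spec 85.42
  µmol/L/min tabulated default, 68.42 available as a named preset;
  Km 65.6 µmol/L) plus GFR filtration `GFR·fu·C` (GFR 0.12 L/min, on by
  default, minor next to secretion);
* glyburide — linear hepatic clearance on unbound drug (fu = 0.01).

The bridging constants (central/peripheral volumes, inter-compartment flow,
`secretion_scale` or `cl_hepatic`, and metformin's transporter
`capacity_scale`) are identified by staged Monte-Carlo random search
(`analysis/02_calibrate_models.py`, fixed seeds) minimising the summed
squared log-error of simulated Cmax and AUC0–t against the reference-arm
geometric means (metformin 1215.67 ng/mL, 5770.53 ng·h/mL; glyburide
67.44 ng/mL, 408.98 ng·h/mL).  Achieved errors: metformin 2.0% / 1.5%,
glyburide 0.2% / 4.3%.  The winners are frozen as presets.  Glyburide's
small apparent central volume (~1 L) absorbs the bioavailability bridging of
the reduced model and should not be read as a physiological volume.

Integration uses LSODA with rtol 1e−8 / atol 1e−10 by default; the
right-hand side is built purely from transfers, so the dose-fraction ledger
(residual solid, luminal dissolved, in body, eliminated, fecal) closes to
solver tolerance — in practice to machine precision — at every output time.
Amounts are carried in µmol internally; plasma output is ng/mL via the
molecular weight.  Population-level runs use rtol 1e−6 and a coarser output
grid (5–15 min), which changes the reported metrics by far less than the
effects under study.

## Virtual population and crossover

Each of `n` virtual subjects carries two independently drawn GI states — the
within-subject variability of the trial — and one disposition set held
constant across periods, so that formulation differences are expressed only
through the absorption environment.  GI parameters are uniform within
configurable ranges (stomach pH 1.3–2.5, duodenum 5.8–6.5, jejunum 6.0–7.0,
ileum 6.8–7.5, colon 5.5–7.0, rectum 6.5–7.5; liquid GET 10–30 min, solid
GET 15–60 min, SITT 2–5 h, LITT 10–40 h).  Demographics (age 18–60, BMI
19–27) are recorded metadata; the reduced disposition does not scale with
them — a documented limitation relative to a whole-body model.  Subjects are
randomly split into balanced TR/RT sequences (period 1 uses GI state 1,
period 2 state 2; each sequence is stratified into GI1/GI2 subgroups as
design metadata), and every (subject, period, treatment) cell is simulated
deterministically.

Bioequivalence per metric is the standard fixed-effects crossover ANOVA on
the log metric (treatment + period + subject; for a complete balanced 2×2
this coincides with the paired period-difference analysis — verified against
a closed-form oracle in the tests).  The 90% CI of the geometric mean ratio
must lie within 80.00–125.00% (two one-sided tests); the combination passes
only if Cmax and AUC0–t pass for both components.  No multiplicity
adjustment is applied, matching regulatory practice for the fixed TOST
bounds.

## Sensitivity and safe space

Local sensitivity uses the dimensionless relative coefficient
`S = (ΔPK/ΔP)·(P/PK)` from one-at-a-time +10% perturbations (a central ±10%
option exists and is used where a symmetric estimate matters, e.g. the
AUC-vs-clearance check, whose exact value is −1 for linear elimination).
Parameters with |S| < 0.05 for every output are flagged for exclusion from
population variability.  In the calibrated models, metformin exposure is
governed by transit times and its saturable elimination, and is essentially
pH-insensitive; glyburide is dominated by small-intestinal pH (jejunum >
ileum > duodenum) with colonic pH affecting AUC0–t — the expected contrast
between a highly soluble, carrier-absorbed base and a poorly soluble weak
acid.

The safe-space search varies the 50%-dissolution time of virtual test
batches (shape and lag held fixed) over a coarse 5-min grid, refines each
pass/fail transition by bisection to 1-min resolution, and reuses the same
population, design, and pre-computed reference arm at every point so that
differences are formulation-driven only.  The reported bounds are the
outermost passing td50 values; an edge is flagged "open" when the pass
region reaches the scanned range limit.

## Problem sizes

The full analyses (`analysis/05`, `analysis/06`) use the 100-subject trial
size.  The test suite scales most population runs down to 6–24 subjects,
with one exception: the shared glyburide safe-space scan runs at the full
100 subjects, because with this component's large within-subject variability
the crossover GMR of a finite trial has a randomization scatter of several
percent, and at two dozen subjects that scatter is comparable to the
formulation effect being mapped — an underpowered scan can displace the
pass/fail boundaries by more than the grid resolution.

## What the synthetic data do and do not show

The synthetic-data module generates every input the pipeline consumes: noisy
Weibull-shaped dissolution profiles on the in vitro schedules (6 points to
60 min for metformin, 10 points to 240 min for glyburide; additive Gaussian
noise, default SD 2 percent points, clipped to [0, 105]) and "observed"
concentration–time datasets on the 22-point clinical schedule (0–48 h) with
a conventional proportional + additive residual-error model (CV 10%;
additive 5 ng/mL for metformin, 0.5 ng/mL for glyburide).  Zero-noise
generators are exact inverses of the corresponding fitters, and all
generators are bit-reproducible under a fixed seed.  They emulate the
*structure* of real datasets, not their biology: passing tests demonstrate
the statistical machinery and the model's internal consistency, not
agreement with any particular clinical dataset.

## Known limitations

* No bile-salt micellar solubilisation, so glyburide's in-lumen solubility
  is pure Henderson–Hasselbalch; fast-release batches consequently *gain*
  exposure in this model, and the fast edge of the glyburide safe space is
  set by the Cmax upper CI bound rather than by an AUC loss.  Likewise
  glyburide Tmax is set by transit and the absorption window and barely
  responds to td50 (Cmax carries the release-rate signal instead).
* Metformin exposure is nearly flat for release faster than the reference
  (saturable-uptake-limited regime) and declines for slower release; the
  model does not reproduce an exposure *increase* for moderately slowed
  release.
* Parent compounds only; no metabolites, no enterohepatic recycling, no
  drug–drug interaction between the components; fasted state only; healthy
  (not diabetic) GI physiology.
* Whether the intestinal uptake carrier acts apically only cannot be
  resolved here; a single lumped uptake into the central compartment is
  assumed.
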