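# Methods

## The model

`pembropred` predicts time to progression (TTP) of advanced melanoma under
pembrolizumab from pretreatment data, by personalizing a skeletal
tumor–immune ODE model. The state is (A_pc, T_il, M_el): functional
antigen-presenting cells, effector CD8+ tumor-infiltrating lymphocytes, and
melanoma cells, all in cells:

    dA_pc/dt = alpha_im * M_el/(M_el + b)  -  mu_apc * A_pc
    dT_il/dt = a_pem * alpha_eff * A_pc    -  b_pem * mu_eff * T_il
    dM_el/dt = gamma_mel * M_el            -  nu_mel * T_il * M_el/(M_el + g)

Tumor cells recruit APCs with half-saturation `b`; APCs activate effectors;
effectors kill tumor cells with half-saturation `g`; effectors exhaust at
rate `mu_eff`. The drug has no pharmacokinetics: from treatment start it
multiplies effector activation by `a_pem` and reduces exhaustion by
`b_pem = 0.9`, both held constant. Before treatment the same vector field
with `a_pem = b_pem = 1` describes the untreated host; a simulation may run
the untreated phase on `[t0, t1)` and switch parameters continuously at
`t1` (by default the simulation starts at treatment day 0 directly).

Fixed parameters (units per day or cells):

| parameter | default | note |
|---|---|---|
| alpha_im  | 1862 cells/d | geometric midpoint of the literature range 1.161e3–2.986e3 |
| b         | 7.39e4 cells | geometric midpoint of 3.704e4–1.476e5 |
| mu_apc    | 0.2310 /d | |
| alpha_eff | 0.8318 /d | |
| b_pem     | 0.9 (treated) | not personalized |
| mu_eff    | 0.1777 /d | |
| nu_mel    | 0.1245 /d | |
| g         | 4.49e7 cells | geometric midpoint of 2.019e7–1e8 |

Geometric midpoints are used for range-valued constants because the model is
multiplicative in these scales; all are configurable.

Two parameters are personal. `a_pem` ranges over [10, 1e4] and is fitted on
the natural-log scale (its fitted population distribution is approximately
log-normal). `gamma_mel`, the net growth rate, is dichotomized to
{0.003269, 0.005}/day — derived from melanoma doubling times via
gamma = ln2/Δt — to keep the fit identifiable from short scan series.

## Burden ↔ SOD conversion

Clinical tumor burden is the RECIST 1.1 sum of diameters (SOD, mm). The
model burden is converted by spreading cells over `n_lesions` (1–5) equal
spheres of effective density `rho` cells per mm³ of lesion volume:
`SOD = n * (6V/pi)^(1/3)` with `V = (M/n)/rho`, inverted exactly.

`rho` is a scaling constant, not a histological density. Its default, 15
cells/mm³, places the geometric-mean clinical burden (SOD ≈ 64 mm) at the
model's peak-sensitivity burden `sqrt(b*g) ≈ 1.8e6` cells, where the
immune kill term can actually compete with growth over the whole clinical
SOD range 5–247 mm. At much larger values of `rho` the burden saturates the
kill term and the personal drug effect becomes unidentifiable from SOD
series. Because diameter scales as the cube root of volume, SOD grows as
`exp(gamma*t/3)` in the immune-free limit; one consequence is that with
gamma capped at 0.005/d, a noise-free +20% SOD increase takes at least
~109 days (see Limitations).

## Response evaluation (RECIST 1.1)

Each post-baseline scan receives exactly one category against the baseline
SOD and the nadir (running minimum, baseline included): CR if SOD = 0; PD
if SOD ≥ 1.2 × nadir *and* ≥ nadir + 5 mm; PR if SOD ≤ 0.7 × baseline; SD
otherwise; PD takes precedence over PR. The 5-mm absolute floor can be
disabled (`pd_abs_floor=None`). A decrease of exactly 30% counts as PR.
New lesions are deliberately not a progression trigger: progression is
determined from target-lesion size only. TTP is the day of the first
PD-classified scan (no interpolation), censored at follow-up end, and
discretized into half-open intervals 1: [0,90), 2: [90,150), 3: [150,365)
days, 4: censored or ≥ 365 d (a progression at exactly day 90 is interval 2).

## Per-patient calibration

The simulation is initialized at treatment day 0 with the burden matching
the baseline SOD and the immune compartments at the untreated conditional
equilibrium A* = (alpha_im/mu_apc)·M/(M+b), T* = (alpha_eff/mu_eff)·A*.
(An optional pre-treatment burn-in that solves for an inoculum is provided
but off by default; the initial state of any pre-treatment phase is not
observable from the data.) For each gamma candidate, the sum of squared SOD
residuals over the post-baseline scans (the baseline is matched by
construction and excluded; scans unweighted) is minimized over ln(a_pem)
with bounded Brent search (xatol 1e-4), started at the log-midpoint of the
range (≈ 316 on the natural scale); the candidate pair with smaller SSE
wins, ties toward the smaller gamma, and the reported SSE never exceeds the
initial-guess SSE. Integration uses LSODA with rtol 1e-6 and atol 1 cell.
Fitting is deterministic.

Identifiability: the two personal parameters are jointly identifiable from
noise-free series with several scans over ~a year (the recovery experiment
in the test suite recovers 54/54 on a grid spanning the whole box). They
are *not* identifiable from a single post-baseline scan (one observation,
two parameters), and with 10% multiplicative observation noise the fitted
ln(a_pem) of short series carries 0.3–0.9 ln-units of estimation noise.
This is a property of the data regime, not of the optimizer.

## Covariate personalization

Pretreatment covariates: age, Breslow thickness, LDH, relative lymphocyte
%, baseline SOD, and binary cutaneous/nodular/BRAF-V600 status. Continuous
covariates are min–max normalized per recruiting center (to absorb
between-center assay differences); queries from unseen centers use pooled
bounds; constant features map to 0. Missing continuous values are imputed
with the training mean, missing binaries with 0.

`ln(a_pem)` is estimated by unweighted k-NN regression with
k = ⌊sqrt(n_train)⌋ over normalized features — by default baseline SOD
alone, the covariate most strongly (negatively) associated with the fitted
drug effect. Distance ties break by training order (stable sort).
`gamma_mel` is classified by a depth-2 Gini tree over Breslow thickness and
nodular status (min leaf 3; majority-labeled leaves; hyperparameters are
this package's choice). Validation is leave-one-out: normalization bounds,
imputation values, the neighbor store (k from n−1) and the tree are all
re-learned with the held-out patient removed. Screening utilities (Pearson
r with t-test p-values, descriptive, no multiplicity correction; ROC AUC;
maximal threshold kappa over midpoint thresholds) reproduce the covariate
selection process on any cohort.

## Scoring

Predicted and observed TTP intervals are cross-tabulated (rows predicted,
columns observed) and scored by the multidimensional Cohen's kappa
κ = (p1 − p2)/(1 − p2), with p1 the diagonal proportion and p2 the
matched-category product of the marginals — algebraically the classical
two-rater Cohen's kappa (asserted against an independent implementation to
1e-12). Each patient also receives one of six outcomes: correct interval,
predicted too early, too late, false progression call, missed progression,
agreed non-progression. R² diagnostics use 1 − SS_res/SS_tot against the
identity line (the reference is the equality line, not a refitted slope);
in log mode, pairs containing a zero are dropped first. TTP agreement is
this R² restricted to patients progressing both clinically and in the
prediction.

## Synthetic cohorts

The clinical dataset is not deposited, so the generator emulates the
published 54-patient cohort: age ~ truncated normal (68.5 ± 12 on
[32.5, 91.5] y); Breslow ~ truncated log-normal (median 2.5 mm, σ=1,
[0.37, 28], mean ≈ 4.1); baseline SOD ~ truncated log-normal (median 64 mm,
σ=0.75, [5, 247], mean ≈ 79); LDH and LY% with a configurable per-center
LDH scale; nodular 20%, BRAF 24%, two centers 33:21; per-covariate
missingness equal to the published availability counts. Follow-up is a
truncated log-normal with median 9 months on [2, 35] (the published median
and range); scans fall every 90 ± 14 days, with one end-of-follow-up scan
guaranteed so every record has at least one on-treatment measurement.

Hidden parameters: ln(a_pem) ~ Normal(4.6 − 5.0·x, 0.5) truncated to
[ln 10, ln 1e4], where x is the baseline SOD normalized to its design range
— reproducing the strong negative association between fitted drug benefit
and baseline burden (r ≈ −0.7 at large n) and an approximately log-normal
a_pem; the fast growth class has log-odds −0.6 + 2.5·(normalized Breslow)
+ 1.5·(nodular). These constants were set once so that cohorts match the
published composition (roughly a quarter to a third of patients progress
within follow-up; most censored patients are stable or responding).
Observation: multiplicative log-normal noise (σ = 0.1 by default) on
post-baseline SODs and a 10-mm per-lesion detection floor (sub-threshold
lesions are recorded as 0, producing CR events). Ground truth (parameters,
noise-free TTP interval) is returned in a separate table and never enters
the emitted records.

`parameter_grid_cohort` is a second, deterministic generator used for
identifiability experiments: ln(a_pem) on an even grid over the full range,
alternating growth classes, log-spaced baselines, noise-free scans every
90 days for a year.

What passing tests on these cohorts do *not* show: real scan series have
inter-reader measurement variability, lesion selection ambiguity, new
lesions, non-constant drug exposure and correlated covariates (LDH/LY%/SOD
correlations are unknown and not modeled); the generator's parameter links
are structural assumptions, so cohort-level agreement statistics here
validate the pipeline's internal consistency, not clinical accuracy.

## Pipeline and problem sizes

The `pipeline` stage generates (or reads) a cohort, fits every patient,
screens covariates, and predicts: for each patient the LOO-personalized
parameters drive a simulation assessed on a fixed 90-day grid up to
min(365 d, follow-up end) — prediction is pretreatment, so assessments
follow the planned schedule, not the realized scan dates; a patient
censored before the first scheduled assessment is assessed once at their
own follow-up end. An oracle mode injects the true parameters instead, an
upper bound for the covariate mapping. Outputs are CSV/JSON plus a manifest
(config hash, seed, versions).

Default experiment sizes keep everything desk-scale: cohorts of 54, ten
seeds for the end-to-end check, 50–54 patients for recovery and pooled-R²
checks; a full pipeline run takes a few seconds on one core.

## Numerical choices and degenerate inputs

LSODA (stiff-capable) with rtol 1e-6, atol 1 cell; tiny negative solver
undershoots are clipped to 0 on output. Category boundaries: PR at exactly
30%, PD at exactly +20% with exactly +5 mm, interval edges half-open.
Kappa is undefined (raised) when all mass sits in one matched category
(p2 = 1); R² requires ≥ 2 usable pairs and non-constant observations;
Pearson screening requires ≥ 3 finite pairs and nonzero variance. A
single-class gamma training set yields a warned, constant classifier.
Constant covariates normalize to 0. Seeds fix cohorts bit-for-bit; fitting
and evaluation are deterministic.

## Known limitations

* With gamma ≤ 0.005/d and the spherical conversion, noise-free progression
  inside 0–90 days is impossible (the earliest +20% SOD crossing is day
  ~109), so ground-truth intervals concentrate in {3, 4}; early observed
  progressions arise only through measurement noise. Real cohorts show
  0–90-day progressions, which this model family can only attribute to
  measurement effects.
* Single-scan patients are structurally unidentifiable; their fitted
  ln(a_pem) is essentially the noise projected through the model, which
  caps the achievable LOO R² for ln(a_pem) on default cohorts well below
  the value reported for the real cohort.
* New lesions, irRECIST confirmation, dosing schedules, and additional
  immune compartments are out of scope.
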