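# Methods

## Model

The state is the vector of ten entity counts per 1 µl of simulated
tissue: VC, TAA, B, TH, IL12, IL2, AB, CC, TC, APC.  One time unit is
one 8-hour step (3 steps/day, 21 steps/week); all rates are per step.
The deterministic vector field is

```
dVC   = −(μ1 + α19·TC + α17·AB)·VC
dTAA  = γ21·(μ1 + α19·TC + α17·AB)·VC + γ28·(α88 + α89·TC)·VC
        − (μ2 + α20·APC + α27·AB)·TAA
dB    = γ34·TH + α36·sat(IL2, s3)·B − μ3·B
dTH   = γ40·APC + α46·sat(IL2, s1)·TH + α45·sat(IL12, s2)·TH − μ4·TH
dIL12 = γ51·(μ1 + α19·TC + α17·AB)·VC − (α54·TH + α59·TC + μ5)·IL12
dIL2  = γ64·TH − (α63·B + α69·TC)·IL2 − μ6·IL2
dAB   = γ73·B − (α78·CC + α71·VC + α72·TAA)·AB − μ7·AB
dCC   = [k·(1 − CC/c_max) − α88]·CC − (α89·TC + α87·AB)·CC + p
dTC   = γ91·VC + α96·sat(IL2, s96)·TC − μ9·TC
dAPC  = γ02·TAA − μ0·APC
```

with `sat(x, s) = x/(x+s)`.  Injections are impulses handled outside the
vector field: at every scheduled step the dose q is added to VC before
the step is integrated.

Key structural choices:

- **Antigen supply is carried by the vaccine cells.**  Both release
  terms in the TAA equation are proportional to VC.  We examined the
  alternative in which the secondary release term is carried by CC
  (antigen shed by killed cancer cells).  If that term includes the
  antibody-mediated kill (α87·AB), the loop CC-kill → antigen → APC →
  TH → B → AB → CC-kill has a gain proportional to CC and self-ignites
  with no vaccination at all: an untreated mouse spontaneously raises
  ~10⁵ antibodies and controls its own tumor indefinitely.  If the term
  is carried by CC but restricted to the TC-mediated kill, a treated
  mouse enters a self-sustaining TC–IL2 state and never relapses after
  vaccination ends.  Neither matches the biology being modelled
  (untreated mice die; Early-vaccinated mice relapse), so the VC-carried
  form is used: antigen availability tracks the vaccine, and the immune
  response decays once injections stop.
- **The CC equation groups as logistic growth minus kill plus influx**:
  all CC losses are proportional to CC; the transgenic influx p is an
  absolute rate.
- **α45 stimulates TH through IL12** (with threshold s2), the role the
  parameter is named for; α46 acts through IL2.
- **α72 = α27 = 1e-5**: the antibody–antigen immune-complex binding is
  one process seen from both sides.

## Parameters

Defaults (`default_parameters()`, also emitted as
`default_parameters.csv` by `triplexsim fixtures`): interaction and
release rates as calibrated (e.g. γ21 = 3, γ51 = 10, γ73 = 3,
γ91 = 0.2, α87 = α89 = 4e-5), tumor growth k = 0.0226/step, influx
p = 3 cells/step, capacity c_max = 1e7, dose q = 50 cells/injection,
saturation thresholds s1 = s2 = 1000, s3 = s96 = 400 molecules.

Death/degradation rates are ln(2)/t½.  Half-lives and their units:

| rate | entity | half-life |
|------|--------|-----------|
| μ1, μ2, μ5 | vaccine cells, antigen, IL-12 | 9 steps = 3 days |
| μ6 | IL-2 | 3 steps = 1 day |
| μ4, μ0 | T helper cells, APC | 15 steps = 5 days |
| μ9 | cytotoxic T cells | 21 steps = 7 days |
| μ3 | plasma B cells | 15 **days** = 45 steps |
| μ7 | antibodies | 7 **days** = 21 steps |

The humoral half-lives are read in days because those are the values
the immunology literature quotes for murine IgG (~1 week) and plasma
cells (~2 weeks); an antibody pool with a 2.3-day half-life would decay
within days of the last injection and the Early protocol would relapse
around week 38 instead of the observed ~46–47.  This persistence of the
humoral compartment is the mechanism by which a 3-cycle course protects
for ~30 weeks after the last injection.

## Protocols

All protocols build on a 4-week cycle: injections on days 0, 3, 7, 10
of the cycle (two per week, 3 then 4 days apart — only the relative
spacing is dynamically meaningful), then 14 days of rest.  Treatment
starts at week 6 of age (day 42).  Early = 3 cycles (12 injections,
last on day 108); Chronic = cycles repeating until the horizon
(default end week 57, configurable); Untreated = none.  Injections are
applied at the first 8-hour step of their scheduled day.

## Integration

Classical RK4 on a fixed sub-step grid, 8 sub-steps per 8-hour step by
default.  The system is locally stiff in the high-antibody phases: the
linear loss rate of vaccine cells (α17·AB) reaches tens per step, which
would put λ·h outside the RK4 stability interval (|λ·h| ≲ 2.79) at the
base resolution and make the integration blow up.  Each step therefore
raises its sub-step count to ceil(λ_max/2), where λ_max is the largest
instantaneous linear loss rate over all populations, keeping the
integrator comfortably inside its stability region.  Loss rates of
compartments that are exactly zero and have no active source (e.g. the
antibody pool of an untreated mouse) contribute no dynamics and are
excluded from the stiffness estimate.  Components pushed (negligibly)
below zero by truncation error are clamped to zero and counted; clamp
counts are zero in all default runs.

Accuracy: decoupled exponential-decay and logistic-plus-influx
configurations match analytic/reference solutions to 1e-6 relative;
sub-step halving changes the 57-week untreated trajectory by < 1e-11
(sup-norm, relative).  Treated trajectories traverse the stiff
antibody phases where the guard decouples the effective grid from the
base sub-step count, so pointwise self-convergence there saturates
around 5e-6–5e-5; the death step itself is identical across all tested
sub-step settings.

Death is recorded at the first grid step with CC ≥ 1e5 (inclusive).
`simulate` truncates there by default; sensitivity runs integrate the
full horizon so the output matrix stays rectangular, with
above-threshold values used as-is (flagged as beyond model validity).

## Sensitivity analysis

Latin hypercube sampling: each varied parameter's uniform range is cut
into N equal-probability strata, each sampled once and permuted
independently per parameter (`numpy.random.default_rng(seed)`).  The
default design varies all 40 nonzero immunological parameters —
including the saturation thresholds — over ±50% of their calibrated
values, holds q, k, p, c_max fixed, and appends a uniform(0,1) dummy
parameter with no model effect.  The sampling width is an assumption:
no canonical ranges exist for these rates, and PRCC magnitudes (though
rarely signs) depend on it.

For each LHS row the model is simulated under the Chronic protocol and
the cancer-cell count recorded weekly.  Inputs and outputs are
rank-transformed (average ranks on ties).  The PRCC of parameter j with
the output at time t is the correlation of the residuals of the two
regressions of x_j and y_t on all other parameter columns (the dummy
included).  Significance: t = r·sqrt((N−2−ν)/(1−r²)) with ν = k−1
controlled variables, two-sided, α = 0.01.  An independent oracle —
partial correlation from the inverse rank-correlation matrix — verifies
the residual-regression implementation to 1e-10 in the tests.

Reproducible findings at the default design (N = 200–1000): strong
negative PRCC of γ02, γ21, γ73 and α87 with CC from the first cycles to
the horizon; positive PRCC of μ0; negative PRCC of γ91 and α89 confined
to the first cycles (γ91 loses significance afterwards) — i.e. tumor
control in this model is humorally driven, the cytotoxic branch only
matters while the response is being established.  The dummy stays
non-significant at essentially all time points.  A late-phase positive
PRCC of the immune-complexation rate α72 with CC (antibodies diverted
into binding antigen) is *not* reproduced under the ±50% design: the
measured late PRCC of α72 is ≈ −0.07 to 0 at N = 200–1000, and the
corresponding acceptance test documents the discrepancy by failing.
The count of significant parameters is design-dependent (~20–28 under
the default ranges); the tests report its mean ± sd across seeds rather
than asserting a specific value.

## Problem sizes

Routine tests run the PRCC pipeline at N = 200 over a weekly grid
(0.5–3 min per run on one core — seed-dependent, because LHS draws
whose tumor escapes control are stiff in the antibody equation); the
full N = 1000 design takes ~15 minutes and gives the same signs and
significance patterns.  Survival simulations (57 weeks, 1197 steps)
take ~2–4 s each.

## Known limitations

- No memory B cells (deliberate: chronic vaccination is required for
  protection in this system), no NK population (folded into α88), no
  spatial structure, receptor specificity or antigen escape.
- The model is not valid past the 1e5-cell threshold; trajectories
  continued beyond it are extrapolations.
- Parameter values are point calibrations; only the ±50% LHS design
  quantifies their uncertainty, and the sampling width is itself an
  assumption.
- Protocol timing is resolved to one day; sub-day injection timing is
  arbitrary (first step of the day).
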