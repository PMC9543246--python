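# Methods

## Model structure

The network couples three species — MYC, IRF4 and PRDM1 — each with one
mRNA and one protein variable (a 6-dimensional state), in dimensionless
fold units. Kinetics are two-stage with first-order turnover:

    d m_X / dt = k_m,X · d_X(t) · Π_e g_e(p_source(e)) − γ_m,X · m_X
    d p_X / dt = k_p,X · m_X − γ_p,X · p_X

with degradation rates γ = ln 2 / t_half and the synthesis constants fixed
by the normalization k_m = γ_m, k_p = γ_p, so the all-ones state is an
*exact* fixed point when every regulator is at 1 and no drug is applied.
This matches how both the simulations and the wet-lab readouts are
presented: everything relative to the first timepoint.

Topology (fixed): MYC protein activates IRF4 transcription, IRF4 protein
activates MYC, IRF4 and PRDM1 transcription, and PRDM1 protein represses
MYC transcription. Multiple regulators combine multiplicatively on the
transcription rate (independent-binding assumption; the underlying
experiments constrain no particular combination rule).

## Regulation algebra

Each edge applies a Hill-type factor normalized to 1 at the steady state.
With threshold K > 0, Hill coefficient h > 0 and maximum fold effect
w ≥ 1:

* activation: g(x) = (1 − a) + a · x^h (1 + K^h) / (x^h + K^h), with
  a = (w − 1)/K^h. Then g(0) = 1 − a (basal floor), g(1) = 1,
  g(∞) = w; a ∈ [0, 1] requires w ≤ 1 + K^h.
* repression: g(x) = (1 − b) + b · (1 + K^h) / (K^h + x^h), with
  b = (w − 1) K^h. Then g(0) = w, g(1) = 1, g(∞) = 1 − b; b ∈ [0, 1]
  requires w ≤ 1 + K^(−h).

The fold-strength parameterization is a convex combination of the constant
1-function and the fully-scaled Hill form; at the defaults K = 1, h = 1,
w = 2 it reduces to g(x) = 2x/(1+x) (activation) and 2/(1+x) (repression).
The exact functional form of regulated transcription is a modeling choice
of this package: the underlying study constrains only the signs of the
edges and the fold-change presentation, so we picked the simplest form for
which the all-ones steady state is exact, and flag it as an interpretation.

## Parameters

Hours are the canonical time unit everywhere (minutes accepted in config
files with an explicit `min` suffix).

Protein half-lives (the constants the model is built around):

| preset         | MYC      | IRF4  | PRDM1 |
|----------------|----------|-------|-------|
| initial_model  | 0.5 h    | 7 h   | 7 h   |
| updated_model  | 0.5 h    | 48 h  | 7 h   |
| KMS-12-BM      | 1 h      | 61 h  | 7 h   |
| NCI-H929       | 22 min   | 52 h  | 7 h   |
| SKMM-1         | 30 min   | 33 h  | 7 h   |

mRNA half-lives are assumptions, not measurements: MYC 0.5 h, IRF4 2 h,
PRDM1 2 h (config-exposed). The short MYC mRNA half-life is needed for the
rapid MYC mRNA drop seen in drug-treatment qPCR; the others are generic
short-mRNA values. The PRDM1 protein half-life (7 h) is likewise an
assumption. Changing any of these requires only a config edit, no code.

Drug action: targeted transcription terms are multiplied by (1 − ε) from
the onset time (default 0) as a hard switch; the integrator is restarted
at the onset so the discontinuity never crosses a solver step. The default
inhibition fraction ε = 0.8 represents a strong but incomplete
transcriptional block; exactness checks use ε = 1, which makes the
targeted mRNA/protein pair a closed linear subsystem with the
variation-of-constants solution used as the test oracle.

Hill defaults: h = 1, K = 1, w = 2 for all edges (config-exposed).

## Numerics

`scipy.integrate.solve_ivp` with LSODA (stiff-capable; rate constants span
22 minutes to 61 hours), rtol 1e−8, atol 1e−10, dense output evaluated on
the requested grid and retained for off-grid queries (model values at data
timepoints always come from dense output, never nearest-grid snapping).
State is never clipped inside the solver; outputs are clipped at 0, and
regulator arguments are clamped at 0 during RHS evaluation only, to guard
against transient integration undershoot. Solver failure raises with the
solver's diagnostics rather than returning partial output.

The cycloheximide chase sets every translation rate k_p to 0, which makes
each protein ODE autonomous: p_X(t) = exp(−γ_p,X t) exactly. The chase
therefore takes protein values from this closed form and integrates only
the 3-dimensional mRNA subsystem (whose regulators are the analytically
decaying proteins). This keeps the chase → half-life-estimator round trip
exact to regression precision instead of solver tolerance.

## Half-life estimation

Ordinary least squares of ln(signal) on time over all pooled replicate
points; k = −slope, t_half = ln 2 / k, goodness reported as R² of the
log-linear fit. Chosen over a nonlinear exponential fit because it is the
standard treatment of chase densitometry, closed-form and deterministic.
Nonpositive signals (densitometry floor) are dropped before the log
transform with a warning, never imputed; at least 3 positive points are
required. A non-decaying series (slope ≥ 0) returns an infinite half-life
with a `no_decay` flag rather than a silent number. Replicates are pooled
by concatenation rather than fit-per-replicate-then-average; with 3
replicates both are defensible and one had to be chosen.

Default chase sampling: 0/8/24/48/72 h for long-lived proteins, with
sub-hour points (0/0.25/0.5/1/2 h) when a short-lived protein (MYC) is the
object of interest — a protein with a 30-minute half-life is at 2^(−16) of
baseline by 8 h, far below any realistic detection floor.

## Discrepancy scoring and scenario ranking

Each replicate is divided by its own first-timepoint value (error if that
value is nonpositive, naming the replicate); means and sample SDs
(n − 1 denominator) are computed per timepoint. The fit readout is the
per-timepoint squared distance (model_t − mean_t)², summed per
species/analyte. For programmatic ranking of the three drug-target
scenarios (MYC, IRF4, MYC+IRF4) these sums are added across all
species/analytes with equal weights into a grand total — the equal-weight
scalar aggregation is this package's addition; the per-series distances
are the primitive quantity. Scenarios are ranked by grand total ascending
with ties broken by lexicographic label order. Housekeeping (β-actin)
normalization is upstream wet-lab processing and out of scope: inputs are
assumed to be already-ratioed positive values.

## Dose–response fitting

Four-parameter logistic on log10 dose,
y = bottom + (top − bottom)/(1 + 10^((log d − log IC50)·hill)), fit by
least squares (`scipy.optimize.curve_fit`) with the deterministic
initialization top = max response, bottom = min response, IC50 =
geometric mid-dose, slope = 1. A response range below 1e−9 is flagged
degenerate and not fitted; an IC50 outside the dose span is flagged
extrapolated. Replicates are pooled by default (per-replicate fits behind
a flag). No synergy statistic is computed.

## Synthetic data

The generators emulate the statistical structure of the study's readouts,
not its numbers (the raw data are not public): treatment time courses on
the 0/4/8/24/48/72 h grid with 3 replicates; chase decay tables on the
0/8/24/48/72 h grid; triplicate 4PL viability curves. Abundance noise is
multiplicative lognormal — positive, ratio-scaled, matching qPCR/
densitometry ratios — parameterized mean-one with σ² = ln(1 + CV²),
default CV 10%. Viability noise is additive Gaussian on the percent scale.
Noise is applied at every timepoint *including t = 0*, so fold-change
normalization acts on genuinely noisy baselines. All generators are pure
functions of (configuration, seed) and bit-reproducible.

What passing tests on these data do and do not show: they demonstrate that
the pipeline is self-consistent (parameters used to generate data are
recovered; the generating scenario wins the ranking at the stated rates)
under the declared noise model. Real chase densitometry has correlated
blot-to-blot error, detection floors and possible non-exponential decay
components; real qPCR has plate effects; none of these are emulated, so
recovery rates here are upper bounds on real-data performance.

## Problem sizes

The default analysis scales were chosen to characterize the estimators
well beyond their asymptotic noise floor while remaining quick on a
laptop: 200 seeded chase datasets per half-life for the noisy-recovery
medians, 50 seeded datasets per generating scenario for the
scenario-recovery rate, 100 seeds for noisy IC50 recovery. The full test
suite runs in under a minute.

## Known limitations

* The regulation functional form is an interpretation (see above); only
  its sign structure and steady-state normalization are externally
  constrained.
* Whether distinct per-species mRNA half-lives were used in the original
  simulations is unknowable from the available description; ours are
  declared assumptions.
* The model reproduces the qualitative discrepancy pattern but is not
  expected to close the known gap in IRF4 protein behavior between 24 and
  36 h after treatment — the regulation responsible is an open biological
  question and no attempt is made to model it.
* The drug enters purely as a transcription multiplier; there is no
  chromatin/bromodomain mechanistic layer, no stochastic (SSA) simulation,
  and the KLF2/CDK4/hTERT downstream targets are outside the modeled
  network.
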