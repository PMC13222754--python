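# Methods

`panelnet` implements the statistical pipeline of a three-wave panel
study of parenting behaviors and child irritability across three groups:
psychometric scoring, cross-sectional Gaussian-graphical-model (GGM)
networks, pooled-lag panel graphical vector autoregression (GVAR), and
permutation-based network comparison. Because the motivating cohort data
are access-restricted, the package ships a synthetic generator with
known ground truth, and every estimator is validated by parameter
recovery against that truth.

## Variables and scoring

Six composite variables form the longitudinal network nodes:

| node | instrument | items | item scale | composite |
|---|---|---|---|---|
| `irr` | CBCL irritability items | 3 | 0–2 | mean |
| `pstr` | Aggravation in Parenting | 4 | 1–4, reversed | mean (higher = more stress) |
| `nVio` | CTSPC non-violent discipline | 4 | freq. 0–6 | mean, reversed (higher = fewer occurrences) |
| `psyAgg` | CTSPC psychological aggression | 5 | freq. 0–6 | mean |
| `phyAs` | CTSPC physical assault | 5 | freq. 0–6 | mean |
| `neg` | CTSPC neglect | 5 | freq. 0–6 | mean |

CTSPC raw codes 1–6 are past-year frequency categories; codes 7 ("not in
the past year") and 8 ("never happened") recode to frequency 0. Two
single-item cultural-belonging variables (`cAtt`, `cPra`, 1–4, measured
once at baseline) enter the cross-sectional networks as time-invariant
nodes; they are re-oriented so higher = stronger belonging.

Composites require all of a scale's items by default (`min_items` =
item count). The instruments' missing-item rule is not part of the
public record, and prorating over a subset of items changes composite
variance, so the strict rule is the default and is configurable.

Reliability: McDonald's omega from a one-factor maximum-likelihood fit
on the item covariance, `omega = (Σλ)² / ((Σλ)² + Σθ)`; omega is used
instead of Cronbach's alpha because tau equivalence (equal loadings) is
not assumed — with equal loadings the two coincide, which is one of the
test-suite invariants. Heywood cases (a uniqueness driven to the
boundary) are flagged, not clamped. The two-item cultural pair uses the
Spearman–Brown corrected split-half correlation `2r/(1+r)`.

Descriptives use classical one-way ANOVA (listwise per variable) and
pairwise-complete Pearson correlation matrices; both log the n actually
used. Pairwise deletion mirrors common practice with attrited panels.

## Cross-sectional networks (GGM)

A GGM edge is the partial correlation between two nodes given all
others, `-K_ij/√(K_ii K_jj)` for precision `K`. Sparse networks come
from the graphical lasso (block coordinate descent over the rows of the
precision matrix; only off-diagonal entries are penalized, so the
`λ = 0` limit is the plain inverse covariance). Variables are z-scored
per group × wave first, because partial correlations are scale-free but
the L1 penalty is not.

Model selection: 100 log-spaced penalties spanning
`[0.01·λ_max, λ_max]` with `λ_max = max |off-diagonal covariance|`. The
lasso path proposes candidate edge sets; each distinct support is refit
as a support-constrained Gaussian MLE and the extended BIC,
`-2·loglik + E·log n + 4γ·E·log p` with `γ = 0.5`, compares the refits
(ties break toward sparsity). Scoring unpenalized refits rather than
the shrunken estimates is deliberate: the penalized-EBIC variant admits
many near-zero spurious edges at moderate n (its measured specificity
on an 8-node truth at n = 2000 is ≈ 0.82, versus ≈ 1.0 for refit-based
selection at unchanged sensitivity). The classic behavior is available
via `refit=False`. γ and the grid are configurable since the original
analysis's selection constants are not in the public record.

## Longitudinal model (panel GVAR)

Scores decompose into a stable between-person level and a within-person
deviation following a lag-1 VAR pooled over consecutive wave pairs
(stationarity):

```
y_it = μ + b_i + w_it,   w_{i,t+1} = B w_it + ζ_it
b_i ~ N(0, Σ_b),         ζ_it ~ N(0, Σ_ζ)
```

Three networks result: the directed temporal network `B` (row =
outcome, column = predictor; diagonal = autoregressive stability), the
contemporaneous network (partial correlations of the innovations), and
the between-person network (partial correlations of the person levels).
The two covariances are parameterized as `Σ = Δ(I − Ω)⁻¹Δ` with `Ω` the
partial-correlation matrix, so one parameter = one edge.

Estimation is Gaussian ML on the stacked 18-dimensional observation
(6 nodes × 3 waves). The implied covariance has blocks
`Cov(y_t, y_s) = B^{t−s} S + Σ_b` (t ≥ s), where `S` solves the
discrete Lyapunov equation `S = B S Bᵀ + Σ_ζ` (solved by LU of
`I − B⊗B`). Means are treated as saturated and the discrepancy
`F = log|Σ| + tr(SₙΣ⁻¹) − log|Sₙ| − 18` is minimized by L-BFGS with an
**analytic gradient**: the Lyapunov solve is differentiated through its
adjoint equation (`Ḡ = BᵀḠB + G`, reusing the transposed LU factors),
which is what makes bootstrap and permutation procedures affordable.
The gradient is verified against finite differences in the test suite.
Starting values are moment-based (pooled lag-1 regression of
person-centered deviations; covariances eigen-floored away from
singularity). A failed line of descent triggers one retry from a
neutral diagonal start; convergence is judged by the optimizer status
and gradient norm.

Numerical notes: with only three waves, a high autoregression and a
between-person trait are weakly distinguished; at small n (≈ 200/group)
the ML solution can legitimately drift toward a collapsed between
component, which the fit reports honestly through large Wald standard
errors rather than hiding. The unequal age spacing (3→5 vs 5→9 years)
is ignored by the pooled lag-1 treatment — a modeling assumption
inherited from the design, not a bug.

Fit: `χ² = (n−1)F` against the saturated (free 18×18 covariance) model;
CFI/TLI against the independence baseline (free variances only,
df = 153); RMSEA = `√(max(χ²−df,0)/(df(n−1)))`. The baseline is stated
explicitly because incremental indices depend on it. df = 171 − free
parameters (saturated pattern: 78, so df = 93).

Pruning: iterated Wald tests. Each round fixes to zero every free
structural edge (temporal entries including autoregressions,
contemporaneous and between-person partials) with `p ≥ α`, refits, and
repeats until nothing is removable. `α = 0.01` by default (the
convention of this estimator family; the original α is unpublished).
Standard errors come from the inverse Hessian of the discrepancy
(finite differences of the analytic gradient), scaled by `2/(n−1)`.

Stability: case bootstrap — persons resampled with replacement, all of
a person's waves travelling together — with R replicates of the full
fit→prune pipeline. An edge's inclusion proportion is the fraction of
successful replicates where it survives pruning; edges below the 0.5
threshold are masked from the reported "stable" network. The boundary
is inclusive (exactly 50% counts as stable). Failed replicates are
dropped from the denominator and reported.

`temporal_std` reports `B` on a unit-free scale,
`std_ij = B_ij·√(S_jj/S_ii)` with `S` the stationary within-person
covariance: the effect per predictor SD in outcome SDs. For a scalar
AR(1) this equals the lag-1 autocorrelation; for a unit-variance
process it equals `B`. Raw and standardized matrices are both emitted
because reporting conventions differ.

## Permutation comparisons

The comparison statistic is the absolute edge difference (AED) between
two independently estimated networks. The null permutes group labels
over whole persons (preserving within-person dependence) and
re-estimates both networks with the identical estimator per
permutation; `p = (1 + #{perm ≥ obs})/(1 + n_perm)` (add-one rule, so
`p ≥ 1/(n_perm+1)` and the test is valid at any permutation count). The
omnibus statistic is the maximum AED with its own permutation p-value.
For the longitudinal test the statistic is the difference of pruned
edge estimates, an edge pruned away contributing 0 ("not included in
network" convention); each permutation recomputes the full fit→prune
statistic, which is what makes observed and null statistics
exchangeable. The cross-timepoint test permutes the two wave labels
within person (paired permutation) — a reconstruction of an unpublished
procedure, and an approximation under temporal dependence, both stated
here deliberately.

A calibration caveat: for an edge absent from the generating model the
lasso estimate is exactly zero in both groups with high probability, the
observed AED ties at 0, and the add-one p-value is 1 — the per-edge test
is conservative (rejects less than α), never anti-conservative, at such
edges. Level-α behavior holds for edges actually present; the
calibration tests evaluate the rejection rate there.

Holm step-down adjustment is reported alongside raw p-values (the
original correction method is unstated; raw p drives the significance
stars, `^ <.10, * <.05, ** <.01, *** <.001`).

## Synthetic generator

`default_truth` encodes the study-shaped conditions: group sizes
1167/614/627; wave retention (0.9857, 0.9016) matching 1.43% and 9.84%
wave-over-wave attrition (monotone dropout — a person missing a wave is
missing all later waves); group mean shifts reproducing the reported
descriptive orderings; a shared lag-1 dynamic with cross-lagged edges of
0.05–0.35 echoing the reported partial-correlation range (e.g. physical
assault → irritability 0.15, neglect → non-violent discipline 0.30);
contemporaneous and between-person networks with a handful of edges;
Likert item measurement with loadings tuned so omegas land in the
0.6–0.9 band the instruments show; and the inclusion filter
(irritability at ≥ 2 waves), applied once before all estimation, with
excluded persons flagged rather than dropped. Scenarios: `shared`
(identical dynamics across groups), `group_divergent` (two named
temporal edges shifted by +0.30 in group G2), `null` (autoregression
only). Within-person processes start at their stationary distribution,
so three waves suffice without burn-in. One master seed spawns
per-stage substreams (levels, dynamics, items, missingness).

`benchmark_truth` is a second, unit-scale truth used for
estimator-property benchmarks (pruning calibration, bootstrap
stability): all nodes on a common scale so edge magnitudes are directly
comparable, with a strong (0.40), moderate (0.30) and small (0.15)
temporal effect plus true zeros. The study-shaped truth deliberately
keeps unequal instrument scales — there, an edge like neglect →
non-violent discipline is weakly estimable because neglect has little
variance, which is realistic and is reflected in its standard errors.

What the generator does *not* emulate: the cohort's city
stratification and 3:1 oversampling design, respondent switching
(mother vs other caregiver), floor effects beyond simple clipping of
the Gaussian composites at instrument bounds (< ~1% of mass under the
default truth), and non-monotone item-level missingness. Passing
recovery tests therefore demonstrate estimator correctness under the
model's own assumptions, not robustness to those survey features.

## Problem sizes and determinism

Monte-Carlo sizes used by the test suite are chosen for a desk run:
GGM recovery at n = 2000 × 20 replicates; GVAR recovery at
n = 1000 × 10 seeds; pruning calibration at 40 replicates; bootstrap
stability at R = 100 × 10 outer replicates; comparison-test level at
130 simulations × 200 permutations, and longitudinal power at 10
replicates × 100 permutations. The pipeline's desk defaults are
R = n_perm = 200 with `--paper-scale` switching to 1000/1000.
`scripts/acceptance.py` runs the full pipeline at 400 persons per group
with R = n_perm = 100. All randomness flows from explicit seeds through
`numpy.random.SeedSequence` spawns; reports contain no timestamps, so a
rerun under one config is byte-identical.

## Known limitations

- The GVAR assumes multivariate normality of composites; Likert-derived
  composites are only approximately so.
- T = 3 waves is the design optimum; the code accepts other T but the
  between/autoregression identification weakens as T shrinks.
- FIML over monotone missingness patterns is provided but slower
  (numeric gradient) and excluded from fit-index comparisons.
- The paired wave-comparison permutation is approximate under temporal
  dependence (documented above).
- Reported headline estimates of the motivating study are not
  reproducible without its restricted data; validation is
  recovery-based by design.
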