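# Methods

## Model

`birt` implements the one- and two-parameter logistic item response models
for long-format binary data. Each record is a triple (item *i*, taker *j*,
response *r_ij* ∈ {0,1}) and the likelihood is Bernoulli:

    Pr(r_ij = 1) = logistic(z_ij),   z_ij = θ_j − β_i         (1PL)
                                     z_ij = α_i (θ_j − β_i)   (2PL)

θ_j is taker ability, β_i item difficulty, α_i item discrimination
(strictly positive). Priors are independent normals whose **second
hyperparameter is a variance**: θ_j, β_i ~ N(0, var 2) and
log α_i ~ N(0.5, var 1). The hyperparameters are exposed on `ModelSpec`, so
an sd-parameterized variant can be configured if a user needs to match
software that reads the second argument as a standard deviation.

Per-record log-likelihood uses the overflow-safe form
`r·z − log(1 + e^z)` (`np.logaddexp`), valid for |z| up to the float range.
`log_likelihood` sums in canonical (item, taker) order so the value is
bit-identical regardless of record storage order. Fitting requires every
item and every taker to appear in at least one record; the 2PL model
without discrimination parameters is a configuration error, not a silent
fallback.

## Sampler

The engine is a componentwise adaptive random-walk Metropolis-within-Gibbs
sampler operating on the unconstrained vector (θ, β, a = log α). Because the
prior on *a* is placed on the log scale directly, no Jacobian correction is
needed.

Design points:

* **Blocked vectorized sweeps.** Conditional on the item parameters, the
  θ_j are mutually independent (and symmetrically for β and a given the
  rest), so one sweep proposes Gaussian moves for a whole block at once and
  applies per-coordinate accept/reject with grouped likelihood deltas
  (`bincount` over the records touching each coordinate). This is exact
  Metropolis-within-Gibbs, just evaluated without Python-level loops; a
  sweep costs a handful of O(n_records) array operations.
* **Adaptation.** Per-coordinate log step sizes follow a Robbins–Monro
  recursion `log s += t^(−0.6) · (acc_prob − 0.44)` during warmup, using the
  smooth acceptance probability min(1, e^Δ) rather than the accept
  indicator; steps are frozen after warmup so retained draws come from a
  fixed kernel. The 0.44 target is the standard optimum for one-dimensional
  random-walk updates. Post-warmup per-coordinate mean acceptance is
  recorded and lands in roughly [0.35, 0.55] on realistic posteriors.
* **Determinism.** The master seed spawns one `numpy` `SeedSequence`
  substream per chain; chains run sequentially and identical inputs give
  bit-identical draws. Warmup draws are never retained.
* **Initialization.** Chains start from independent prior draws by default
  (dispersed starts, which is what the convergence diagnostics assume);
  a zeros initialization is available. A non-finite starting density is
  retried up to 100 times before erroring.
* **Validation.** The identical kernel runs against arbitrary black-box
  log-densities (`sample_logpdf`); tests check closed-form moment recovery
  on a Normal(1, var 4) target and Kolmogorov–Smirnov agreement (< 0.02 at
  50k draws) on a two-parameter product-normal target, plus split-R-hat
  < 1.01 for all abilities at 6 chains × 8000 draws on a 60×7 dataset.

The contract (a `ChainSet` of chains × iterations × parameters with
provenance) is backend-neutral: a gradient-based kernel could be swapped in
without touching diagnostics or agreement code.

## Diagnostics

The summary table follows the standard schema `mean, sd, hdi_3%, hdi_97%,
ess_bulk, ess_tail, r_hat`, computed on the constrained scale (α = e^a):

* **HDI**: shortest contiguous window of the sorted pooled sample
  containing ⌈mass·n⌉ points, leftmost window on ties; mass defaults
  to 0.94 (hence the 3%/97% column labels) and is configurable.
* **split R-hat**: each chain is split in half, pooled draws are
  rank-normalized (fractional ranks through the normal quantile function
  with the Blom offset (r − 3/8)/(N + 1/4)), and the classical
  between/within variance ratio is taken over the 2m half-chains.
  Constant draws return exactly 1.0 by convention.
* **ESS (bulk/tail)**: Geyer initial-monotone-sequence estimator on the
  combined per-chain autocovariances (FFT), after rank normalization of
  split chains for the bulk version; tail ESS is the minimum over the 5%
  and 95% quantile indicator sequences. Constant draws return 0 (no
  information) and are logged. The implementation numerically matches
  ArviZ's estimators (to ~1e-6 relative in tests); R-hat differs slightly
  from ArviZ's default only because the latter additionally folds the
  draws and takes a maximum.
* **sd** uses the n−1 denominator. Export rounds to 3 decimals (ESS to
  integers) to match the conventional printed-table precision; in-memory
  tables keep full precision.

## Agreement

`lin_ccc` implements Lin's (1989) concordance correlation coefficient with
population (1/n) moments:

    ccc = 2 s_xy / (s_x² + s_y² + (x̄ − ȳ)²)

Moment convention matters only through the mean-shift term (n−1 factors
cancel elsewhere), and 1/n follows the original definition. Edge cases are
pinned: elementwise-identical inputs return exactly 1.0; two constant
sequences return 1.0 if equal, else 0.0. Classification applies **after
rounding to 3 decimals**, which makes the printed bands well-defined:
< 0.900 poor, 0.900–0.950 moderate, 0.951–0.990 substantial,
> 0.990 almost perfect.

`compare_summaries` matches parameters by name (optionally filtered by a
regex such as `^theta`) and errors loudly on any roster mismatch.

## Synthetic data

The real BONE (60 patients × 7 radiologists) and BRAIN (42 × 14) rating
data are not redistributable, so the generator emulates them with a
two-step scheme:

1. **Latent parameters** either from the model priors, or — for the
  BONE-like/BRAIN-like presets — abilities drawn from independent normal
  approximations N(mean_j, sd_j²) to published per-taker posterior
  summaries, which are packaged as a fixture CSV
  (`birt/data/reference_summaries.csv`, three estimation runs × four
  dataset/model combinations). Item parameters always fall back to prior
  draws because the published summaries omit item rows.
2. **Responses** as one Bernoulli(logistic(z_ij)) draw per cell of the full
  item × taker grid.

The **scaling ladder** multiplies the number of takers by
f ∈ {1, 2, 5, 10, 20, 50, 100, 200, 500, 1000} with items fixed; replicate
k of base taker j redraws θ from that taker's normal approximation. Scaling
takers (rather than items) reproduces the benchmark totals
420…420,000 / 588…588,000 exactly and keeps item parameters comparable
across scales; it is a documented stand-in, not a claim about how the
original benchmark data were enlarged.

What the generator does **not** emulate: missing or unbalanced designs,
rater drift over cases, correlations between ability and case mix, or
multi-modality reading conditions. Passing parameter-recovery tests on
these data therefore demonstrates sampler and estimator correctness under
the model's own assumptions, not robustness to real-world model violation.

## Engine recommendation

`recommend_engine` encodes a size-based advisory: up to the original-size
regime (t1 = 588, the larger base roster) a compiled reference engine tends
to win on startup cost; between t1 and t2 a vectorized CPU engine; above
t2 = 40,000 (midpoint of the empirically reported 30,000–50,000 crossover
band) a GPU engine. Both thresholds are arguments/flags; the rule is
qualitative and the timing harness (`birt benchmark`) records but never
asserts wall-clock numbers, which are hardware-dependent.

## Problem sizes used in the test suite

Tests favour the smallest sizes at which each property is sharp: oracle
equivalence on ~100 random 1–6 × 1–4 rosters; closed-form target checks at
20k–50k draws; convergence at 6 × 8000 on the 420-response roster;
parameter recovery on 21,000 responses (60 items × 350 takers, 2 chains ×
3000 + 500 warmup) with CCC ≥ 0.90 and ≥ 85% HDI coverage of true
abilities; the agreement-vs-draws trend at 10/160/5120 retained draws per
chain with 6 chains. The full suite runs in about a minute on one CPU.

## Known limitations

* Random-walk Metropolis mixes adequately at these scales but is not
  competitive with gradient-based samplers for very large rosters; the
  backend-neutral contract exists precisely so a NUTS-style kernel could be
  slotted in.
* The posterior-summary normal approximation ignores posterior skew and
  cross-parameter correlation.
* ESS/R-hat estimator variants differ slightly across libraries; the
  testable contract here is the iid and AR(1) limits plus cross-library
  numerical agreement, not bit-equality with any one tool.
* 3PL, graded-response and nominal models are out of scope.
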