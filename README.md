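# birt — Bayesian item response theory for rater agreement studies

`birt` fits Bayesian one- and two-parameter logistic item response (IRT)
models to long-format binary response data, the setting where *test items*
are patient cases and *test takers* are the clinicians rating them.  It was
built around a concrete methodological question: when the same IRT model is
estimated twice by independent MCMC runs (different software backends,
different seeds, different draw budgets), how well do the estimated ability
parameters agree, and how does the answer scale with dataset size?

The package provides:

* **Model core** — the 1PL/2PL logistic likelihood and its priors.  For
  taker $j$ and item $i$ the probability of a correct response is

  $$\Pr(r_{ij}=1) = \frac{1}{1+e^{-z_{ij}}}, \qquad
    z_{ij} = \begin{cases}\theta_j-\beta_i & \text{(1PL)}\\
    \alpha_i(\theta_j-\beta_i) & \text{(2PL)}\end{cases}$$

  with priors $\theta_j,\beta_i \sim N(0,\,\mathrm{var}\,2)$ and
  $\log\alpha_i \sim N(0.5,\,\mathrm{var}\,1)$.
* **Sampler** — a self-contained, fully deterministic (seeded)
  componentwise adaptive random-walk Metropolis engine that exploits the
  conditional independence of the IRT posterior to update whole parameter
  blocks vectorized.
* **Diagnostics** — posterior summary tables in the standard
  `mean, sd, hdi_3%, hdi_97%, ess_bulk, ess_tail, r_hat` schema
  (94% highest-density intervals, rank-normalized split R-hat, bulk/tail
  effective sample sizes).
* **Agreement** — Lin's concordance correlation coefficient (CCC) between
  two summary tables, with the conventional classification
  (poor < 0.900, moderate 0.900–0.950, substantial 0.951–0.990,
  almost perfect > 0.990).
* **Synthetic data** — generators emulating two published radiology rating
  rosters (BONE-like: 60 patients × 7 raters = 420 responses; BRAIN-like:
  42 × 14 = 588), plus a 1×–1000× taker-scaling ladder for computational
  benchmarking, and the published per-taker posterior summaries packaged as
  fixtures.
* **CLI** — `birt fit | simulate | summarize | agree | benchmark |
  recommend`, each writing a reproducibility manifest.

## Worked example

Fit a 1PL model to a synthetic BONE-like dataset twice with different seeds
and measure agreement of the estimated abilities:

```bash
birt fit --dataset BONE_LIKE --model 1PL --chains 6 --samples 8000 \
         --warmup 2000 --seed 11 --out run_a
birt fit --dataset BONE_LIKE --model 1PL --chains 6 --samples 8000 \
         --warmup 2000 --seed 12 --out run_b
birt agree --a run_a/summary.csv --b run_b/summary.csv \
           --data-label BONE --model-label 1PL --out report.csv
```

The `agree` command prints

```
ccc=0.999610 label=almost_perfect n=7
```

meaning the seven posterior-mean abilities from the two independent runs lie
on the identity line with a concordance of 0.9996 — the two runs are
interchangeable for practical purposes, the same conclusion the agreement
classification expresses with the label `almost_perfect`.  `run_a/summary.csv`
contains one row per parameter, e.g.

```
name,mean,sd,hdi_3%,hdi_97%,ess_bulk,ess_tail,r_hat
theta[0],1.809,0.407,1.05,2.578,6065,9676,1.0
```

read as: posterior mean ability 1.809 ± 0.407, 94% HDI (1.05, 2.578), thousands
of effective draws and split-R-hat 1.0, i.e. well-mixed chains.

For dataset-size planning, `birt recommend 42000` prints `gpu`: an advisory
rule that a compiled reference engine is fastest at original-size data
(≤ ~600 responses), a vectorized CPU engine up to ~40,000, and a GPU engine
beyond.

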