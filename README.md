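# recombkit

Statistical toolkit for studying how a genetic variant reshapes meiotic
recombination and associates with a binary reproductive outcome — built
around crossover interference, per-meiosis recombination phenotypes and
case/control meta-analysis, with a fully seeded synthetic-data generator
so that every analysis runs without access to individual-level human
data.

It is aimed at statistical geneticists who want a tested, reproducible
reference implementation of these analyses: the crossover process model
and its exact likelihood are written here from first principles, while
routine steps (OLS/WLS, logistic IRLS, rank statistics, exact binomial
tests) use scipy/statsmodels.

## The models

**Crossover interference (gamma-escape model).** Crossovers on a
chromosome of genetic length *L* Morgans arise from two independent
pathways: a stationary gamma renewal chiasma process with shape *ν* and
rate 2ν(1−p) per Morgan, thinned by the 1/2 chromatid choice
(interference pathway), plus a homogeneous Poisson process of intensity
*p* (escape pathway). Total intensity is exactly 1 per Morgan for every
(ν, p). Larger ν means more evenly spaced crossovers; ν = 1, p = 0 is a
homogeneous Poisson process. The package evaluates the exact likelihood
of observed crossover positions (summing over all pathway assignments
with an O(n²) dynamic program), fits (ν, p) by joint maximum
likelihood, and compares carrier and noncarrier groups with a
likelihood-ratio test on a χ² distribution with 2 degrees of freedom.

**Recombination phenotypes.** Per meiosis, genome-wide and per
chromosome: crossover count (RR), hotspot fraction (RH), normalized
telomere distance (TD), and mean GC content / replication timing in a
1-kb window around each crossover (GC, RT). Phenotypes are rank-
inverse-normal transformed, associated additively with allele dosage by
OLS, and per-chromosome effects are regressed on chromosome length with
inverse-variance weights (the length-interaction analysis).

**Meta-analysis.** Per-cohort logistic regression of case status on
dosage, pooled by fixed-effects inverse variance with Cochran's Q
heterogeneity, class-based weighted-Bonferroni thresholds and an exact
binomial enrichment test.

## Worked example

```python
import numpy as np
from recombkit import (StahlParams, simulate_stahl_process, fit_stahl,
    simulate_case_control_cohorts, cohort_summaries, ivw_meta)

# recover interference parameters from simulated meioses
rng = np.random.default_rng(1)
truth = StahlParams(nu=6.59, p=0.039)
records = [(L, simulate_stahl_process(truth, L, rng))
           for _ in range(2000) for L in (1.5, 2.0, 2.5)]
fit = fit_stahl(records)
print(f"nu_hat = {fit.nu_hat:.2f}, p_hat = {fit.p_hat:.3f}, "
      f"loglik = {fit.loglik:.1f}, crossovers = {fit.n_crossovers}")

# meta-analysis of simulated low-frequency case/control cohorts
tables = simulate_case_control_cohorts(
    [(5000, 20000)] * 4, [0.002, 0.005, 0.009, 0.013], true_or=1.22, seed=1)
m = ivw_meta(cohort_summaries(tables))
print(f"OR = {m.or_:.2f} (95% CI {m.ci_low:.2f}-{m.ci_high:.2f}), "
      f"P = {m.p:.2g}, P_het = {m.p_het:.2f}")
```

prints

```
nu_hat = 6.71, p_hat = 0.039, loglik = -10073.8, crossovers = 12108
OR = 1.33 (95% CI 1.18-1.50), P = 2.2e-06, P_het = 0.21
```

From 12,108 simulated crossovers the joint MLE lands within 2% of the
generating interference shape (6.71 vs 6.59) and recovers the escape
proportion almost exactly; the pooled odds ratio from one seeded
four-cohort simulation covers the generating value 1.22 inside its 95%
CI, with no detectable between-cohort heterogeneity (P_het = 0.21).

A YAML-configured pipeline runs every stage end to end and writes
checksummed, provenance-stamped TSVs:

```sh
recombkit run-all --config config.yaml --seed 7 --out results/
```

Subcommands `genome`, `simulate`, `phenotypes`, `interference` and
`meta` run individual stages on intermediate files. See
`docs/methods.md` for the model details, defaults and limitations.

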