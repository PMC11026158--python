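# Methods

## Scope

`recombkit` re-implements, on synthetic data, the statistical machinery
used to characterize how a low-frequency variant reshapes meiotic
recombination and associates with a binary reproductive outcome:

1. a generative model of crossover placement with interference
   (gamma-renewal chiasma process with an interference-free escape
   pathway), and exact maximum-likelihood inference of its parameters;
2. construction of per-meiosis recombination phenotypes and additive
   genotype-phenotype association, genome-wide and per chromosome, with
   a chromosome-length interaction regression;
3. per-cohort logistic case/control association pooled by fixed-effects
   inverse-variance meta-analysis, with class-based weighted-Bonferroni
   significance thresholds and an exact binomial enrichment test.

Individual-level human data are not used anywhere; a fully seeded
synthetic-data module generates every input.

## Crossover model

Crossovers on a chromosome of genetic length `L` Morgans are the
superposition of two independent processes:

* **Interference pathway.** Chiasmata on the four-strand bundle follow a
  stationary gamma renewal process with shape `nu` and rate
  `2 nu (1 - p)` per Morgan. Each chiasma is transmitted on a given
  chromatid with probability 1/2 (thinning). `nu > 1` makes successive
  crossovers more regularly spaced than Poisson; `nu = 1` is no
  interference.
* **Escape pathway.** A homogeneous Poisson process of intensity `p`
  per Morgan, representing crossovers that form without sensing
  interference.

The thinned renewal pathway has intensity `1 - p`, so total crossover
intensity is exactly 1 per Morgan for every `(nu, p)` — the calibration
that defines genetic distance. The inter-crossover gap on the
interference pathway is the geometric gamma mixture

    f(x) = sum_{k>=1} 2^{-k} Gamma(x; k nu, 2 nu (1 - p)),

with mean `1/(1-p)`; the stationary first-point density is
`h(x) = (1 - p)(1 - F(x))` and the empty-interval probability
`P0(L) = 1 - int_0^L h`.

**Simulation.** Stationarity is achieved by burn-in: the renewal chain
starts at an epoch 20 mean inter-chiasma gaps to the left of the
chromosome, far beyond the relaxation distance of a gamma renewal
process; the residual bias is invisible against the closed-form
empty-interval probability and all Poisson reductions in the test suite.
Crossovers are emitted as exact points on the genetic axis and mapped to
base pairs through the genome model (real crossover calls are resolved
to marker intervals; interval censoring is future work).

**Likelihood.** Observed crossovers carry no pathway label, so the
likelihood of `y_1 < ... < y_n` sums over every assignment of points to
the interference pathway:

    lik = e^{-pL} sum_S p^{n-|S|} [ P0(L) if S empty else
          h(s_1) prod f(gaps) (1 - F(L - s_last)) ].

The sum is evaluated with an O(n^2) dynamic program over the rightmost
interference-assigned point, vectorized across all meiosis-chromosome
records with the same crossover count, never by 2^n enumeration (a
brute-force enumerator exists only as a test oracle). `F` and
`int_0^L F` have closed forms in regularized incomplete gamma functions
(`int_0^x P(a,t) dt = x P(a,x) - a P(a+1,x)`), so no quadrature is
needed. The geometric series is truncated at K = 54 terms (tail mass
2^-54 ~ 5.6e-17); this keeps the `nu = 1` identity — total log-likelihood
exactly `-(total Morgans)` — true to 1e-8 even summed over cohort-scale
record counts, which a looser truncation does not.

**Fitting.** `(nu, p)` are estimated jointly in the unconstrained
parametrization `(ln nu, logit p)`: a coarse grid (default 5 x 5) picks
the best start and Nelder-Mead refines it; `logit p` is floored at -12,
which represents the `p = 0` boundary. Chromosomes share one `(nu, p)`
within a group. The carrier/noncarrier contrast is a likelihood-ratio
test: `chi2 = 2 (ll_carrier + ll_noncarrier - ll_pooled)` referred to a
chi-squared distribution with 2 degrees of freedom; tiny negative values
from optimizer tolerance are clamped to 0. Observed-information standard
errors (central differences) are optional and suppressed at the `p`
boundary.

## Genome model and phenotypes

A genome is an ordered set of chromosomes, each with physical length,
a monotone piecewise-linear bp <-> cM map anchored at `(0, 0)` and the
chromosome end, optional hotspot intervals, and binned GC/replication
tracks. Coordinates are 0-based, half-open; on a cM plateau the
genetic-to-physical inversion returns the left endpoint. Hotspots are
maximal runs of fixed-width bins (default 10 kb; the width is a
parameter because published maps do not pin it down) whose local rate is
at least `fold` (default 10) times the genome-average cM/Mb.

Per meiosis and per scope (genome-wide or one chromosome):

* `RR` — crossover count;
* `RH` — fraction of crossovers inside hotspot intervals;
* `TD` — mean of `min(pos, length - pos) / length` over crossovers
  (normalization by full chromosome length, so TD is in [0, 0.5]; only
  the carrier/noncarrier contrast matters downstream, so the choice of
  constant is immaterial but stated);
* `GC`, `RT` — mean of the track average in a 1,000-bp window centred on
  each crossover, clipped at chromosome ends.

Location phenotypes are missing when `RR = 0` in scope; missing rows are
dropped per phenotype before the rank-based inverse-normal transform
`Phi^-1((r - 0.5)/m)` with average ranks for ties (the Blom offset would
change nothing detectable at cohort sizes; the simpler offset is stated
for reproducibility).

## Association and interaction

Association is OLS of the rank-normalized phenotype on allele dosage
(plus optional covariates), two-sided t-test p-values; effects are in
s.d. units with `beta_raw = beta x raw per-scope SD` for native units.
Per-chromosome effects feed a weighted least-squares regression of
`beta_c` on chromosome length `l_c` (Mb) with weights `1/var(beta_c)` —
inverse variance is the standard reading of using "effects and their
variances" as regression input. Shifting all effects by a constant
changes only the intercept; the slope (per Mb) is the length-interaction
estimate.

## Case/control simulation and meta-analysis

Cohort genotypes are Binomial(2, q) under Hardy-Weinberg; case status is
Bernoulli with `logit P = alpha_c + dosage ln(OR)`, `alpha_c` calibrated
per cohort by Brent root finding so the expected case fraction matches
the target. Per-cohort effects come from maximum-likelihood logistic
regression (IRLS via statsmodels) with Wald p-values and a divergence
guard against separation. Pooling is fixed-effects inverse variance
(`w_i = 1/se_i^2`), heterogeneity by Cochran's Q with `k - 1` df; no
random-effects model is offered because the target design is fixed
effects. Class-based thresholds are `alpha w_c / sum n_c' w_c'`,
conserving `sum n_c threshold_c = alpha` exactly; the published class
weights are configuration, not constants. The enrichment test is an
exact binomial tail, one-sided upper by default with sidedness as a flag
(published analyses do not always state the convention).

## Carrier effects in the generator

`CarrierEffectSpec` carries Stahl parameters per dosage (additive
construction: heterozygotes at the carrier estimate, homozygotes at
twice the per-allele displacement, values clipped to valid ranges) and
an optional distal-shift strength `theta_c = a + b l_c` per allele.
The distal shift is a monotone power-family warp of the normalized
genetic coordinate toward the chromosome ends
(`t -> sign(t)|t|^{1/(1+theta)}` on `t = 2u - 1`), preserving endpoints
and total map length, so a known-sign telomere-ward effect — optionally
growing with chromosome length — can be injected to exercise the TD and
interaction stages.

## What the synthetic data do and do not emulate

Emulated: interference and escape with distinct carrier/noncarrier
parameters; Hardy-Weinberg carrier sampling at low allele frequency;
length-coupled map distortion; case/control cohorts sharing one
per-allele odds ratio with cohort-specific frequencies and case
fractions. Not emulated: genotyping/imputation error, relatedness and
population structure, interval-censored crossover calls, paternal
meioses, covariate structure of real cohorts (age, region, principal
components). Passing tests therefore validate the estimators under the
stated model, not robustness to those real-data complications.

## Problem sizes and numerical choices

Parameter-recovery runs use 3,000 meioses on five chromosomes of
1.0-3.0 Morgans (about 30,000 crossovers), which puts the joint MLE
within a few percent of the truth; null calibrations use 200 seeded
replicates with 150 meioses per group (LRT) or 300 meioses on six
chromosomes (interaction slope), sizes at which one calibration run
completes in a few seconds while the Wilks chi-squared approximation is
already accurate. Null-calibration simulations use interior parameters
(`nu = 5, p = 0.08`): with small per-seed samples a true `p` close to 0
occasionally pins the estimate to the boundary and distorts the Wilks
reference distribution for reasons unrelated to the code under test.
Meta-analysis recovery uses 4 cohorts of 5,000 cases / 20,000 controls
at risk-allele frequencies 0.2-1.3%. Optimizer tolerances are
`xatol = 1e-4` on `(ln nu, logit p)` and `fatol = 1e-7` on the
log-likelihood (calibration loops relax these to `5e-4`/`1e-6` with a
3 x 3 start grid; the LRT statistic changes by < 1e-4). Degenerate
inputs — empty groups, `p = 1` (no interference pathway), zero-variance
weights, rank-deficient designs, separation — raise informative errors
rather than returning numbers.

## Known limitations

* The likelihood treats crossover positions as exact; marker-interval
  censoring is not modelled.
* `fit_stahl` assumes parameters shared across chromosomes within a
  group; chromosome-specific interference is out of scope.
* The per-record crossover count is guarded at 25 (far above anything a
  human-scale genetic length produces; larger values indicate corrupted
  input rather than biology).
* Wilks-based LRT p-values are asymptotic; at very small cohort sizes,
  or with a true escape proportion at the boundary, they are only
  approximate.
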