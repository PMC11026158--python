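"""Additive genotype-phenotype association and the chromosome-length
interaction regression.

The association model is ordinary least squares of a rank-normalized
phenotype on allele dosage (0/1/2) plus optional covariates, so effects
are reported in s.d. units of the transformed phenotype; a parallel
``beta_raw`` converts back to native units (Mb for telomere distance,
cM for recombination rate) by multiplying with the raw per-scope
phenotype SD.

Per-chromosome effects feed a weighted linear regression of effect size
on chromosome length (weights = inverse variance of the per-chromosome
estimates), the interaction analysis that asks whether an allele
re-shapes recombination differently on long and short chromosomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genome import GenomeModel
from .phenotypes import GENOME_SCOPE, scope_raw_sd

__all__ = [
    "AssocResult",
    "ChromEffect",
    "InteractionFit",
    "additive_assoc",
    "per_chromosome_effects",
    "length_interaction",
]

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300


@dataclass
class AssocResult:
    beta: float
    se: float
    p: float
    n: int


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # find a culprit column: the first whose removal restores full rank
        for j in range(X.shape[1]):
            sub = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                raise ValueError(f"design matrix is rank deficient: column {names[j]!r} is collinear")
        raise ValueError("design matrix is rank deficient")


def additive_assoc(
    y, dosage, covariates: pd.DataFrame | np.ndarray | None = None
) -> AssocResult:
    """OLS of phenotype on dosage (plus covariates); two-sided t-test p.

    Missing phenotype values are dropped.  A numerically perfect fit
    (zero residual variance) is reported with ``se = 0`` and the p-value
    floored at ~1e-300.
    """
    y = np.asarray(y, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cov_names = (
            list(covariates.columns)
            if isinstance(covariates, pd.DataFrame)
            else [f"cov{i}" for i in range(cov.shape[1])]
        )
    else:
        cov = np.empty((len(y), 0))
        cov_names = []
    ok = ~np.isnan(y)
    y, dosage, cov = y[ok], dosage[ok], cov[ok]
    n = len(y)
    n_params = 2 + cov.shape[1]
    if n <= n_params:
        raise ValueError(f"n = {n} too small for {n_params}-parameter model")
    X = np.column_stack([np.ones(n), dosage, cov])
    _check_rank(X, ["intercept", "dosage", *cov_names])
    fit = sm.OLS(y, X).fit()
    beta, se = float(fit.params[1]), float(fit.bse[1])
    if fit.ssr < 1e-12 * max(float(np.sum(y**2)), 1.0):
        return AssocResult(beta=beta, se=0.0, p=_P_FLOOR, n=n)
    return AssocResult(beta=beta, se=se, p=max(float(fit.pvalues[1]), _P_FLOOR), n=n)


@dataclass
class ChromEffect:
    """Per-chromosome additive effect of the focal allele.

    ``beta`` is in s.d. units of the rank-normalized phenotype;
    ``beta_raw`` in the phenotype's native units (beta times the raw
    per-scope SD).  ``ci95`` is ``beta +/- 1.96 se``.
    """

    chrom: str
    phenotype: str
    beta: float
    se: float
    p: float
    n: int
    beta_raw: float
    length_mb: float

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.beta - 1.96 * self.se, self.beta + 1.96 * self.se)


def per_chromosome_effects(
    pheno_table: pd.DataFrame,
    genome: GenomeModel,
    phenotype: str,
    covariates: pd.DataFrame | None = None,
) -> list[ChromEffect]:
    """Additive association of each chromosome-scope phenotype with
    dosage.  Chromosomes whose phenotype is entirely missing are omitted
    with a warning."""
    col = f"{phenotype}_rin"
    if col not in pheno_table.columns:
        raise ValueError(f"phenotype table lacks {col!r}; run add_rank_normalized first")
    effects = []
    for chrom in genome:
        try:
            sub = pheno_table.xs(chrom.name, level="scope")
        except KeyError:
            logger.warning("no phenotype rows for chromosome %s; omitted", chrom.name)
            continue
        y = sub[col].to_numpy(dtype=float)
        if np.all(np.isnan(y)):
            logger.warning("%s on %s all missing; omitted", phenotype, chrom.name)
            continue
        res = additive_assoc(y, sub["dosage"].to_numpy(), covariates)
        raw_sd = scope_raw_sd(pheno_table, phenotype, chrom.name)
        effects.append(
            ChromEffect(
                chrom=chrom.name,
                phenotype=phenotype,
                beta=res.beta,
                se=res.se,
                p=res.p,
                n=res.n,
                beta_raw=res.beta * raw_sd,
                length_mb=chrom.length_mb,
            )
        )
    return effects


@dataclass
class InteractionFit:
    """Weighted regression of per-chromosome effects on chromosome length."""

    slope: float  # per Mb
    se: float
    p: float
    intercept: float
    n_chromosomes: int


def length_interaction(
    effects: list[ChromEffect], lengths_mb: list[float] | None = None
) -> InteractionFit:
    """WLS of ``beta_c`` on chromosome length ``l_c`` with weights
    ``1 / var(beta_c)``; the slope tests whether the allelic effect
    scales with chromosome length."""
    if len(effects) < 3:
        raise ValueError("need >= 3 chromosomes for the interaction regression")
    betas = np.array([e.beta for e in effects])
    ses = np.array([e.se for e in effects])
    if np.any(ses <= 0):
        raise ValueError("zero-variance effect estimate; cannot weight")
    if lengths_mb is None:
        lengths = np.array([e.length_mb for e in effects])
    else:
        lengths = np.asarray(lengths_mb, dtype=float)
    X = sm.add_constant(lengths)
    fit = sm.WLS(betas, X, weights=1.0 / ses**2).fit()
    return InteractionFit(
        slope=float(fit.params[1]),
        se=float(fit.bse[1]),
        p=float(fit.pvalues[1]),
        intercept=float(fit.params[0]),
        n_chromosomes=len(effects),
    )


def effects_to_frame(effects: list[ChromEffect]) -> pd.DataFrame:
    """Tidy per-chromosome effect table (for the TSV writers)."""
    return pd.DataFrame(
        {
            "chrom": [e.chrom for e in effects],
            "phenotype": [e.phenotype for e in effects],
            "length_mb": [e.length_mb for e in effects],
            "beta_sd": [e.beta for e in effects],
            "se": [e.se for e in effects],
            "p": [e.p for e in effects],
            "beta_raw": [e.beta_raw for e in effects],
            "n": [e.n for e in effects],
        }
    )
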