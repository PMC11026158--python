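"""Case-control association and fixed-effects meta-analysis.

Per-cohort effects come from maximum-likelihood logistic regression of
case status on allele dosage (additive model).  Cohorts are pooled with
the fixed-effects inverse-variance method: weights ``w_i = 1/se_i^2``,
pooled effect ``sum(w b) / sum(w)``, heterogeneity by Cochran's Q
(chi-squared, k-1 df).  Genome-wide significance uses class-based
weighted-Bonferroni thresholds: variants are partitioned into annotation
classes and each class ``c`` gets ``alpha * w_c / sum(n_c' * w_c')``, so
more deleterious (rarer) classes can be given laxer thresholds while the
family-wise budget ``sum n_c * threshold_c = alpha`` is conserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import binomtest, chi2, norm

__all__ = [
    "CohortSummary",
    "MetaResult",
    "ThresholdScheme",
    "logistic_assoc",
    "cohort_summaries",
    "ivw_meta",
    "class_thresholds",
    "binomial_enrichment",
    "filter_sumstats",
    "harmonize_sumstats",
]

logger = logging.getLogger(__name__)

_SEPARATION_BETA = 15.0


@dataclass
class CohortSummary:
    """One cohort's association summary for a single variant."""

    cohort: str
    beta: float  # ln OR per allele
    se: float
    af: float
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"{self.cohort}: se must be positive")
        if not 0.0 < self.af < 1.0:
            raise ValueError(f"{self.cohort}: allele frequency must lie in (0, 1)")


def logistic_assoc(
    dosage, status, covariates: np.ndarray | None = None
) -> tuple[float, float, float]:
    """Logistic regression of case status on dosage; returns
    ``(beta, se, p)`` with a Wald two-sided p-value.

    Raises on apparent separation (diverging coefficient).
    """
    dosage = np.asarray(dosage, dtype=float)
    status = np.asarray(status, dtype=float)
    if set(np.unique(status)) - {0.0, 1.0}:
        raise ValueError("status must be binary 0/1")
    if len(np.unique(status)) < 2:
        raise ValueError("both outcome classes must be present")
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    else:
        cov = np.empty((len(status), 0))
    n_params = 2 + cov.shape[1]
    if len(status) <= n_params:
        raise ValueError("too few observations")
    X = np.column_stack([np.ones(len(status)), dosage, cov])
    fit = sm.GLM(status, X, family=sm.families.Binomial()).fit(maxiter=100)
    beta, se = float(fit.params[1]), float(fit.bse[1])
    if not np.isfinite(beta) or abs(beta) > _SEPARATION_BETA:
        raise ValueError(f"apparent separation: |beta| = {abs(beta):.2f} diverging")
    z = beta / se
    return beta, se, float(2.0 * norm.sf(abs(z)))


def cohort_summaries(tables: pd.DataFrame) -> list[CohortSummary]:
    """Per-cohort logistic association from a tidy genotype/status table
    (columns ``id, dosage, status, cohort``)."""
    out = []
    for cohort, sub in tables.groupby("cohort", sort=True):
        beta, se, _ = logistic_assoc(sub.dosage.to_numpy(), sub.status.to_numpy())
        out.append(
            CohortSummary(
                cohort=str(cohort),
                beta=beta,
                se=se,
                af=float(sub.dosage.mean() / 2.0),
                n_cases=int(sub.status.sum()),
                n_controls=int((1 - sub.status).sum()),
            )
        )
    return out


@dataclass
class MetaResult:
    """Fixed-effects inverse-variance pooled association."""

    beta: float
    se: float
    p: float
    or_: float
    ci_low: float
    ci_high: float
    q: float
    p_het: float
    k_studies: int


def ivw_meta(summaries: list[CohortSummary]) -> MetaResult:
    """Fixed-effects inverse-variance pooling with Cochran's Q."""
    if len(summaries) == 0:
        raise ValueError("need at least one study")
    betas = np.array([s.beta for s in summaries])
    ws = np.array([1.0 / s.se**2 for s in summaries])
    if not np.all(np.isfinite(ws)):
        raise ValueError("non-finite study weight")
    beta = float(np.sum(ws * betas) / np.sum(ws))
    se = float(1.0 / np.sqrt(np.sum(ws)))
    z = beta / se
    q = float(np.sum(ws * (betas - beta) ** 2))
    k = len(summaries)
    p_het = float(chi2.sf(q, df=k - 1)) if k > 1 else 1.0
    return MetaResult(
        beta=beta,
        se=se,
        p=float(2.0 * norm.sf(abs(z))),
        or_=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        q=q,
        p_het=p_het,
        k_studies=k,
    )


@dataclass
class ThresholdScheme:
    """Class-based weighted-Bonferroni significance thresholds."""

    classes: list[str]
    counts: list[int]
    weights: list[float]
    alpha: float
    thresholds: list[float]

    def threshold_for(self, cls: str) -> float:
        return self.thresholds[self.classes.index(cls)]


def class_thresholds(
    counts: dict[str, int], weights: dict[str, float], alpha: float = 0.05
) -> ThresholdScheme:
    """Per-class thresholds ``alpha * w_c / sum(n_c' w_c')``.

    The identity ``sum n_c * threshold_c = alpha`` holds exactly, so the
    scheme spends the family-wise error budget once across all classes.
    """
    if not counts:
        raise ValueError("no variant classes given")
    classes = list(counts)
    n = np.array([counts[c] for c in classes], dtype=float)
    if np.any(n < 1):
        raise ValueError("each class needs at least one variant")
    w = np.array([weights[c] for c in classes], dtype=float)
    if np.any(w <= 0):
        raise ValueError("class weights must be positive")
    denom = float(np.sum(n * w))
    thr = alpha * w / denom
    return ThresholdScheme(
        classes=classes,
        counts=[int(x) for x in n],
        weights=list(map(float, w)),
        alpha=alpha,
        thresholds=list(map(float, thr)),
    )


def binomial_enrichment(
    k_hits: int, n_tests: int, p0: float = 0.05, alternative: str = "greater"
) -> float:
    """Exact binomial test for an excess of nominal hits.

    Default is the one-sided upper tail ``P(X >= k)`` under
    ``X ~ Binomial(n, p0)``; ``alternative`` may be ``"greater"``,
    ``"less"`` or ``"two-sided"``.
    """
    if not 0 <= k_hits <= n_tests:
        raise ValueError("need 0 <= k_hits <= n_tests")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie in (0, 1)")
    return float(binomtest(k_hits, n_tests, p0, alternative=alternative).pvalue)


# -- summary-statistics housekeeping -----------------------------------------


def filter_sumstats(
    df: pd.DataFrame, maf_min: float = 1e-4, info_min: float = 0.8
) -> pd.DataFrame:
    """Row filters conventionally applied before meta-analysis:
    minor-allele frequency >= ``maf_min`` and (when an ``info`` column is
    present) imputation info >= ``info_min``."""
    n0 = len(df)
    maf = np.minimum(df["af"], 1.0 - df["af"])
    keep = maf >= maf_min
    if "info" in df.columns:
        keep &= df["info"] >= info_min
    out = df[keep].copy()
    logger.info("filter_sumstats: %d rows in, %d rows out", n0, len(out))
    return out


def harmonize_sumstats(frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Strict allele harmonization across cohort summary frames.

    Variants are matched on (chrom, pos, ref, alt); rows whose alleles
    appear swapped relative to the first cohort are flipped (beta sign
    and allele frequency), anything else is dropped with a log message.
    """
    if not frames:
        raise ValueError("no summary frames")
    ref_alleles = frames[0].set_index(["chrom", "pos"])[["ref", "alt"]]
    out = [frames[0].copy()]
    for df in frames[1:]:
        df = df.copy()
        keyed = df.set_index(["chrom", "pos"])
        joined = keyed.join(ref_alleles, rsuffix="_ref", how="inner")
        same = (joined.ref == joined.ref_ref) & (joined.alt == joined.alt_ref)
        flipped = (joined.ref == joined.alt_ref) & (joined.alt == joined.ref_ref)
        dropped = int((~same & ~flipped).sum())
        if dropped:
            logger.info("harmonize_sumstats: dropped %d allele-mismatched rows", dropped)
        flip = joined[flipped].copy()
        flip["beta"] = -flip["beta"]
        flip["af"] = 1.0 - flip["af"]
        flip[["ref", "alt"]] = flip[["alt", "ref"]].to_numpy()
        keep = pd.concat([joined[same], flip])
        out.append(keep.reset_index()[df.columns])
    return pd.concat(out, ignore_index=True)
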