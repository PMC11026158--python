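"""Optional plotting helpers (never on the analysis path).

Two panels mirror the standard ways of looking at a carrier effect on
crossover placement: carrier-vs-noncarrier mean telomere distance per
chromosome with bootstrap CIs, and per-chromosome effect size against
chromosome length with the weighted regression line.
"""

from __future__ import annotations

import numpy as np

from .association import ChromEffect, InteractionFit


def _bootstrap_ci(values: np.ndarray, rng: np.random.Generator, n_boot: int = 2000):
    means = np.array(
        [np.nanmean(rng.choice(values, size=len(values), replace=True)) for _ in range(n_boot)]
    )
    return np.percentile(means, [2.5, 97.5])


def carrier_vs_noncarrier_td(pheno_table, genome, seed: int = 0, ax=None, n_boot: int = 2000):
    """Scatter of per-chromosome mean telomere distance (Mb): carriers on
    y, noncarriers on x, with bootstrap 95% CIs and the y = x line."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    rng = np.random.default_rng(seed)
    for chrom in genome:
        sub = pheno_table.xs(chrom.name, level="scope")
        td_mb = sub["TD"] * chrom.length_mb
        car = td_mb[sub["dosage"] > 0].dropna().to_numpy()
        non = td_mb[sub["dosage"] == 0].dropna().to_numpy()
        if len(car) < 2 or len(non) < 2:
            continue
        ci = _bootstrap_ci(car, rng, n_boot)
        ax.errorbar(
            non.mean(), car.mean(),
            yerr=[[car.mean() - ci[0]], [ci[1] - car.mean()]],
            fmt="o", ms=4, color="tab:blue", ecolor="gray", capsize=2,
        )
    lim = ax.get_xlim()
    ax.plot(lim, lim, "k--", lw=1)
    ax.set_xlabel("noncarrier mean telomere distance (Mb)")
    ax.set_ylabel("carrier mean telomere distance (Mb)")
    return ax


def effect_vs_length(effects: list[ChromEffect], fit: InteractionFit | None = None, ax=None):
    """Per-chromosome effect (s.d. units, 95% CI bars) against chromosome
    length, with the weighted regression line."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ls = np.array([e.length_mb for e in effects])
    bs = np.array([e.beta for e in effects])
    es = np.array([1.96 * e.se for e in effects])
    ax.errorbar(ls, bs, yerr=es, fmt="o", ms=4, color="tab:blue", ecolor="gray", capsize=2)
    ax.axhline(0.0, color="k", lw=0.8)
    if fit is not None:
        xs = np.linspace(ls.min(), ls.max(), 50)
        ax.plot(xs, fit.intercept + fit.slope * xs, color="tab:blue", lw=1.5)
    ax.set_xlabel("chromosome length (Mb)")
    ax.set_ylabel(f"effect on {effects[0].phenotype} (s.d.)")
    return ax
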