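"""Recombination phenotypes computed per meiosis.

Five phenotypes are constructed from the crossovers a parent transmits
to one offspring, genome-wide and per chromosome ("scope"):

* ``RR`` - recombination rate: the number of transmitted crossovers.
* ``RH`` - hotspot usage: the fraction of crossovers falling in
  recombination hotspots (regions whose local rate is ~10x the genomic
  average).
* ``TD`` - telomere distance: the mean distance of crossovers from the
  nearest chromosome end (bp 0 or the chromosome length), normalized by
  the chromosome length, so TD lies in [0, 0.5].
* ``GC`` - mean GC content in a 1,000-bp window centred on each
  crossover.
* ``RT`` - mean replication-timing score in the same window convention.

The four location phenotypes (RH, TD, GC, RT) are undefined (missing)
for a meiosis with no crossover in scope; RR is 0 there.  Phenotypes are
rank-inverse-normal transformed per scope before association testing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .genome import GenomeModel
from .simulate import MeiosisRecord

__all__ = [
    "GENOME_SCOPE",
    "PHENOTYPES",
    "LOCATION_PHENOTYPES",
    "compute_phenotypes",
    "rank_inverse_normal",
    "add_rank_normalized",
    "scope_raw_sd",
    "filter_by_crossover_count",
]

GENOME_SCOPE = "genome"
PHENOTYPES = ("RR", "RH", "TD", "GC", "RT")
LOCATION_PHENOTYPES = ("RH", "TD", "GC", "RT")

_WINDOW_BP = 1000


def _in_intervals(pos: np.ndarray, intervals: list[tuple[int, int]]) -> np.ndarray:
    """Membership of positions in a sorted set of half-open intervals."""
    if not intervals:
        return np.zeros(len(pos), dtype=bool)
    bounds = np.asarray(intervals, dtype=np.int64).ravel()
    # odd insertion index <=> inside an interval
    return np.searchsorted(bounds, pos, side="right") % 2 == 1


def _per_crossover_frame(meioses: list[MeiosisRecord], genome: GenomeModel) -> pd.DataFrame:
    rows = []
    for m in meioses:
        for chrom_name, (bp, cm) in m.crossovers.items():
            if chrom_name not in genome:
                raise ValueError(
                    f"meiosis {m.meiosis_id}: crossover on unknown chromosome {chrom_name!r}"
                )
            if len(bp) == 0:
                continue
            chrom = genome[chrom_name]
            length = chrom.physical_length
            td = np.minimum(bp, length - bp) / length
            hot = _in_intervals(bp, chrom.hotspot_intervals)
            half = _WINDOW_BP // 2
            if chrom.gc_track is not None:
                gc = np.array([chrom.gc_track.mean(x - half, x + half) for x in bp])
            else:
                gc = np.full(len(bp), np.nan)
            if chrom.rt_track is not None:
                rt = np.array([chrom.rt_track.mean(x - half, x + half) for x in bp])
            else:
                rt = np.full(len(bp), np.nan)
            rows.append(
                pd.DataFrame(
                    {
                        "meiosis_id": m.meiosis_id,
                        "chrom": chrom_name,
                        "td": td,
                        "hot": hot.astype(float),
                        "gc": gc,
                        "rt": rt,
                    }
                )
            )
    if not rows:
        return pd.DataFrame(columns=["meiosis_id", "chrom", "td", "hot", "gc", "rt"])
    return pd.concat(rows, ignore_index=True)


def compute_phenotypes(
    meioses: list[MeiosisRecord],
    genome: GenomeModel,
    scopes: str | list[str] = "all",
) -> pd.DataFrame:
    """Phenotype table with one row per (meiosis, scope).

    ``scopes`` is ``"all"`` (genome plus every chromosome), ``"genome"``,
    a chromosome name, or an explicit list.  Returns a DataFrame indexed
    by ``(meiosis_id, scope)`` with columns RR, RH, TD, GC, RT and a
    ``dosage`` column carried from the meiosis records.
    """
    if scopes == "all":
        scope_list = [GENOME_SCOPE] + genome.names
    elif isinstance(scopes, str):
        scope_list = [scopes]
    else:
        scope_list = list(scopes)
    for s in scope_list:
        if s != GENOME_SCOPE and s not in genome:
            raise ValueError(f"unknown scope {s!r}")

    xo = _per_crossover_frame(meioses, genome)
    ids = [m.meiosis_id for m in meioses]
    dosages = pd.Series([m.dosage for m in meioses], index=pd.Index(ids, name="meiosis_id"))

    agg_cols = {"td": "TD", "hot": "RH", "gc": "GC", "rt": "RT"}
    frames = []
    for scope in scope_list:
        sub = xo if scope == GENOME_SCOPE else xo[xo.chrom == scope]
        if len(sub):
            grouped = sub.groupby("meiosis_id")
            agg = grouped[list(agg_cols)].mean().rename(columns=agg_cols)
            agg["RR"] = grouped.size()
        else:
            agg = pd.DataFrame(columns=[*agg_cols.values(), "RR"])
        agg = agg.reindex(ids)
        agg["RR"] = pd.to_numeric(agg["RR"], errors="coerce").fillna(0).astype(int)
        agg["scope"] = scope
        agg["dosage"] = dosages
        frames.append(agg.reset_index().rename(columns={"index": "meiosis_id"}))
    table = pd.concat(frames, ignore_index=True)
    table["meiosis_id"] = table["meiosis_id"].astype(str)
    return table.set_index(["meiosis_id", "scope"])[
        ["dosage", "RR", "RH", "TD", "GC", "RT"]
    ]


def rank_inverse_normal(values) -> np.ndarray:
    """Rank-based inverse-normal transform.

    Non-missing values are replaced by ``Phi^-1((r - 0.5) / m)`` where
    ``r`` is the (average-tie) rank among the ``m`` non-missing values;
    missing values stay missing.  Requires at least two non-missing
    values.
    """
    x = np.asarray(values, dtype=float)
    out = np.full_like(x, np.nan)
    ok = ~np.isnan(x)
    m = int(ok.sum())
    if m < 2:
        raise ValueError(f"need >= 2 non-missing values, got {m}")
    ranks = rankdata(x[ok], method="average")
    out[ok] = norm.ppf((ranks - 0.5) / m)
    return out


def add_rank_normalized(table: pd.DataFrame) -> pd.DataFrame:
    """Append ``*_rin`` columns: each phenotype rank-normalized within
    its scope (missing rows dropped per phenotype first)."""
    table = table.copy()
    for pheno in PHENOTYPES:
        table[f"{pheno}_rin"] = np.nan
        for scope, idx in table.groupby(level="scope").groups.items():
            vals = table.loc[idx, pheno].to_numpy(dtype=float)
            if np.sum(~np.isnan(vals)) >= 2:
                table.loc[idx, f"{pheno}_rin"] = rank_inverse_normal(vals)
    return table


def scope_raw_sd(table: pd.DataFrame, phenotype: str, scope: str) -> float:
    """SD of the untransformed phenotype within a scope (for converting
    effects from s.d. units back to native units)."""
    vals = table.xs(scope, level="scope")[phenotype].dropna()
    return float(vals.std(ddof=1))


def filter_by_crossover_count(
    meioses: list[MeiosisRecord], chrom: str, mode: str
) -> list[MeiosisRecord]:
    """Subset meioses by their crossover count on one chromosome.

    ``mode`` is ``"exactly_one"`` or ``"more_than_one"``; together with
    the zero-crossover meioses the two modes partition the input.
    """
    if mode not in ("exactly_one", "more_than_one"):
        raise ValueError(f"unknown mode {mode!r}")
    out = []
    for m in meioses:
        n = m.n_crossovers(chrom)
        if (mode == "exactly_one" and n == 1) or (mode == "more_than_one" and n > 1):
            out.append(m)
    return out
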