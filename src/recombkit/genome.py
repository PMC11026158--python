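"""Genome representation for crossover analyses.

A :class:`GenomeModel` holds an ordered set of chromosomes, each with a
physical length in base pairs, a monotone piecewise-linear genetic map
(bp <-> cM anchors), an optional set of recombination-hotspot intervals,
and optional binned GC-content and replication-timing tracks.

Coordinates are 0-based with half-open ``[start, end)`` intervals.
Physical positions are integers (base pairs); genetic positions are
floating centimorgans.  The first map anchor of every chromosome is
``(0 bp, 0 cM)`` and the last anchor sits at the chromosome end, so the
whole chromosome is mappable in both directions.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CoordinateError",
    "BinnedTrack",
    "ChromosomeModel",
    "GenomeModel",
    "hotspot_mask",
    "grch38_autosome_lengths",
    "load_genome",
    "read_chrom_sizes",
    "read_genetic_map",
    "read_bed_intervals",
    "read_track",
    "write_bed_intervals",
]


class CoordinateError(ValueError):
    """A position fell outside the span of a chromosome."""


@dataclass
class BinnedTrack:
    """Piecewise-constant genomic track (bedGraph-style bins).

    Bins must tile the chromosome: contiguous, sorted, covering
    ``[0, chromosome length)``.
    """

    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.starts) == len(self.ends) == len(self.values)):
            raise ValueError("track arrays must have equal length")
        if len(self.starts) == 0:
            raise ValueError("track must have at least one bin")
        if np.any(self.ends <= self.starts):
            raise ValueError("track bins must have positive width")
        if np.any(self.starts[1:] != self.ends[:-1]):
            raise ValueError("track bins must be contiguous and sorted")

    @property
    def span(self) -> tuple[int, int]:
        return int(self.starts[0]), int(self.ends[-1])

    def mean(self, start: int, end: int) -> float:
        """Length-weighted mean of the track over ``[start, end)``.

        The window is clipped to the track span; an empty (clipped)
        window raises ``ValueError``.
        """
        lo, hi = self.span
        start = max(int(start), lo)
        end = min(int(end), hi)
        if end <= start:
            raise ValueError(f"empty interval [{start}, {end}) after clipping")
        i0 = int(np.searchsorted(self.ends, start, side="right"))
        i1 = int(np.searchsorted(self.starts, end, side="left"))
        s = self.starts[i0:i1].astype(float).copy()
        e = self.ends[i0:i1].astype(float).copy()
        s[0] = max(s[0], start)
        e[-1] = min(e[-1], end)
        w = e - s
        return float(np.sum(w * self.values[i0:i1]) / np.sum(w))


def _validate_anchors(anchors: np.ndarray, name: str, length: int) -> np.ndarray:
    anchors = np.asarray(anchors, dtype=float)
    if anchors.ndim != 2 or anchors.shape[1] != 2 or anchors.shape[0] < 2:
        raise ValueError(f"{name}: need >= 2 (bp, cM) anchors")
    bp, cm = anchors[:, 0], anchors[:, 1]
    if bp[0] != 0 or cm[0] != 0:
        raise ValueError(f"{name}: first map anchor must be (0 bp, 0 cM)")
    if np.any(np.diff(bp) <= 0):
        raise ValueError(f"{name}: anchor bp positions must be strictly increasing")
    if np.any(np.diff(cm) < 0):
        raise ValueError(f"{name}: anchor cM positions must be non-decreasing")
    if bp[-1] != length:
        raise ValueError(f"{name}: last anchor must sit at the chromosome end ({length} bp)")
    return anchors


@dataclass
class ChromosomeModel:
    """One chromosome: physical span, genetic map, hotspots and tracks."""

    name: str
    physical_length: int
    map_anchors: np.ndarray  # (k, 2) columns bp, cM
    hotspot_intervals: list[tuple[int, int]] = field(default_factory=list)
    gc_track: BinnedTrack | None = None
    rt_track: BinnedTrack | None = None

    def __post_init__(self) -> None:
        self.physical_length = int(self.physical_length)
        if self.physical_length <= 0:
            raise ValueError(f"{self.name}: physical length must be positive")
        self.map_anchors = _validate_anchors(self.map_anchors, self.name, self.physical_length)
        for s, e in self.hotspot_intervals:
            if not (0 <= s < e <= self.physical_length):
                raise ValueError(f"{self.name}: hotspot [{s}, {e}) outside chromosome")

    @property
    def genetic_length_cm(self) -> float:
        return float(self.map_anchors[-1, 1])

    @property
    def genetic_length_morgans(self) -> float:
        return self.genetic_length_cm / 100.0

    @property
    def length_mb(self) -> float:
        return self.physical_length / 1e6

    # -- coordinate conversion ------------------------------------------------

    def phys_to_gen(self, pos):
        """bp -> cM by piecewise-linear interpolation between anchors."""
        pos_arr = np.asarray(pos, dtype=float)
        if np.any(pos_arr < 0) or np.any(pos_arr > self.physical_length):
            raise CoordinateError(
                f"{self.name}: physical position outside [0, {self.physical_length}]"
            )
        out = np.interp(pos_arr, self.map_anchors[:, 0], self.map_anchors[:, 1])
        return float(out) if np.isscalar(pos) or pos_arr.ndim == 0 else out

    def gen_to_phys(self, cm):
        """cM -> bp.  On a flat map segment (cM plateau) the preimage is an
        interval; the left endpoint is returned (documented tie-break)."""
        cm_arr = np.atleast_1d(np.asarray(cm, dtype=float))
        bp_a, cm_a = self.map_anchors[:, 0], self.map_anchors[:, 1]
        total = cm_a[-1]
        if np.any(cm_arr < 0) or np.any(cm_arr > total):
            raise CoordinateError(f"{self.name}: genetic position outside [0, {total}] cM")
        # first anchor index with cm_a[i] >= target: the preimage lies in
        # segment (i-1, i], and linear inversion there is the leftmost bp.
        idx = np.searchsorted(cm_a, cm_arr, side="left")
        out = np.empty_like(cm_arr)
        at0 = idx == 0
        out[at0] = bp_a[0]
        seg = idx[~at0] - 1
        c0, c1 = cm_a[seg], cm_a[seg + 1]
        b0, b1 = bp_a[seg], bp_a[seg + 1]
        frac = np.where(c1 > c0, (cm_arr[~at0] - c0) / np.where(c1 > c0, c1 - c0, 1.0), 1.0)
        out[~at0] = b0 + frac * (b1 - b0)
        return float(out[0]) if np.isscalar(cm) or np.asarray(cm).ndim == 0 else out

    def map_convert(self, pos, direction: str):
        """Convert ``pos`` between coordinates; ``direction`` is
        ``"phys_to_gen"`` or ``"gen_to_phys"``."""
        if direction == "phys_to_gen":
            return self.phys_to_gen(pos)
        if direction == "gen_to_phys":
            return self.gen_to_phys(pos)
        raise ValueError(f"unknown direction {direction!r}")

    def local_rate(self, start: int, end: int) -> float:
        """Mean recombination rate (cM/Mb) over ``[start, end)``."""
        if end <= start:
            raise ValueError("empty interval")
        d_cm = self.phys_to_gen(end) - self.phys_to_gen(start)
        return d_cm / ((end - start) / 1e6)


@dataclass
class GenomeModel:
    """Ordered collection of chromosomes with genome-wide summaries."""

    chromosomes: list[ChromosomeModel]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        self._by_name = {c.name: c for c in self.chromosomes}

    def __getitem__(self, name: str) -> ChromosomeModel:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def total_physical_length(self) -> int:
        return sum(c.physical_length for c in self.chromosomes)

    @property
    def total_genetic_length_cm(self) -> float:
        return sum(c.genetic_length_cm for c in self.chromosomes)

    @property
    def genome_average_rate(self) -> float:
        """Genome-wide average recombination rate in cM/Mb."""
        return self.total_genetic_length_cm / (self.total_physical_length / 1e6)


def hotspot_mask(
    chrom: ChromosomeModel,
    genome: GenomeModel,
    fold: float = 10.0,
    bin_bp: int = 10_000,
) -> list[tuple[int, int]]:
    """Call recombination hotspots on one chromosome.

    A hotspot is a maximal run of fixed-width bins whose local rate
    (cM/Mb) is at least ``fold`` times the genome-wide average rate.
    The field convention for human maps is a 10x threshold; the bin
    width used to evaluate the local rate is configurable (10 kb by
    default).  The result is also stored on ``chrom.hotspot_intervals``.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    if chrom.genetic_length_cm == 0 and genome.total_genetic_length_cm == 0:
        raise ValueError("zero-length genetic map")
    edges = np.arange(0, chrom.physical_length + bin_bp, bin_bp, dtype=np.int64)
    edges[-1] = chrom.physical_length
    if edges[-1] == edges[-2]:
        edges = edges[:-1]
    cm_at = chrom.phys_to_gen(edges.astype(float))
    widths_mb = np.diff(edges) / 1e6
    rates = np.diff(cm_at) / widths_mb
    threshold = fold * genome.genome_average_rate
    hot = rates >= threshold
    intervals: list[tuple[int, int]] = []
    i = 0
    n = len(hot)
    while i < n:
        if hot[i]:
            j = i
            while j + 1 < n and hot[j + 1]:
                j += 1
            intervals.append((int(edges[i]), int(edges[j + 1])))
            i = j + 1
        else:
            i += 1
    chrom.hotspot_intervals = intervals
    return intervals


# -- file I/O (TSV / BED dialects) -------------------------------------------


def read_chrom_sizes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["chrom", "length_bp"])
    df["chrom"] = df["chrom"].astype(str)
    return df


def read_genetic_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("chrom", "pos_bp", "cM"):
        if col not in df.columns:
            raise ValueError(f"genetic map {path}: missing column {col!r}")
    return df


def read_bed_intervals(path) -> pd.DataFrame:
    """BED3: 0-based, half-open intervals."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
    )
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_bed_intervals(genome: GenomeModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("# hotspot intervals, BED3, 0-based half-open\n")
        for chrom in genome:
            for s, e in chrom.hotspot_intervals:
                fh.write(f"{chrom.name}\t{s}\t{e}\n")


def read_track(path) -> pd.DataFrame:
    """bedGraph-style TSV: chrom, start, end, value (0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "value"],
    )
    df["chrom"] = df["chrom"].astype(str)
    return df


def load_genome(
    chrom_sizes_path,
    genetic_map_path,
    hotspots_path=None,
    gc_track_path=None,
    rt_track_path=None,
) -> GenomeModel:
    """Assemble a :class:`GenomeModel` from the on-disk dialects."""
    sizes = read_chrom_sizes(chrom_sizes_path)
    gmap = read_genetic_map(genetic_map_path)
    hot = read_bed_intervals(hotspots_path) if hotspots_path else None
    gc = read_track(gc_track_path) if gc_track_path else None
    rt = read_track(rt_track_path) if rt_track_path else None

    chroms = []
    for _, row in sizes.iterrows():
        name, length = str(row.chrom), int(row.length_bp)
        sub = gmap[gmap.chrom.astype(str) == name].sort_values("pos_bp")
        if sub.empty:
            raise ValueError(f"genetic map has no anchors for chromosome {name}")
        anchors = sub[["pos_bp", "cM"]].to_numpy(dtype=float)
        intervals = []
        if hot is not None:
            intervals = [
                (int(s), int(e))
                for s, e in hot[hot.chrom == name][["start", "end"]].itertuples(index=False)
            ]
        tracks = {}
        for key, df in (("gc_track", gc), ("rt_track", rt)):
            if df is not None:
                sub_t = df[df.chrom == name].sort_values("start")
                tracks[key] = BinnedTrack(
                    sub_t.start.to_numpy(), sub_t.end.to_numpy(), sub_t.value.to_numpy()
                )
        chroms.append(
            ChromosomeModel(
                name=name,
                physical_length=length,
                map_anchors=anchors,
                hotspot_intervals=intervals,
                **tracks,
            )
        )
    return GenomeModel(chroms)


def grch38_autosome_lengths() -> pd.DataFrame:
    """Bundled GRCh38 autosome lengths (chrom, length_bp)."""
    ref = importlib.resources.files("recombkit.data").joinpath("grch38_autosomes.tsv")
    with importlib.resources.as_file(ref) as path:
        return read_chrom_sizes(path)
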