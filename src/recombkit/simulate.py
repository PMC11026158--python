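"""Synthetic meioses, genomes and case/control cohorts.

The crossover generator implements the two-pathway (gamma-escape,
Housworth-Stahl) model of crossover interference:

* **Interference pathway.**  Chiasmata on the four-strand bundle form a
  stationary gamma renewal process with shape ``nu`` and rate
  ``2 * nu * (1 - p)`` per Morgan (mean inter-chiasma gap
  ``1 / (2 (1 - p))`` Morgans).  Each chiasma involves a given chromatid
  with probability 1/2, so the transmitted crossovers are an independent
  1/2-thinning of the chiasma process.
* **Escape pathway.**  A fraction of crossovers forms without
  interference: a homogeneous Poisson process of retained crossovers
  with intensity ``p`` per Morgan.

The two pathways superpose to a total crossover intensity of exactly
1 per Morgan for every ``(nu, p)``, the defining calibration of the
genetic map.  ``nu = 1`` with ``p = 0`` reduces to homogeneous Poisson
crossovers (no interference).

Stationarity of the renewal pathway is achieved by burn-in: the chain is
started at a renewal epoch ``BURNIN_GAPS`` mean gaps to the left of the
chromosome, far beyond the relaxation distance of the gamma renewal
process.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .genome import BinnedTrack, ChromosomeModel, GenomeModel, hotspot_mask

__all__ = [
    "StahlParams",
    "MeiosisRecord",
    "CarrierEffectSpec",
    "simulate_stahl_process",
    "simulate_meiosis",
    "simulate_recombination_cohort",
    "simulate_case_control_cohorts",
    "synthetic_genome",
    "uniform_rate_genome",
]

#: burn-in length for the stationary start, in mean inter-chiasma gaps
BURNIN_GAPS = 20


@dataclass(frozen=True)
class StahlParams:
    """Interference shape ``nu`` (> 0) and escape proportion ``p`` in [0, 1].

    Larger ``nu`` means more evenly spaced crossovers; ``nu = 1`` is no
    interference.  ``p`` is the fraction of crossovers placed by the
    interference-free pathway.
    """

    nu: float
    p: float

    def __post_init__(self) -> None:
        if not self.nu > 0:
            raise ValueError(f"nu must be positive, got {self.nu}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must lie in [0, 1], got {self.p}")


@dataclass
class MeiosisRecord:
    """One parent-to-offspring transmission.

    ``crossovers`` maps chromosome name to a pair of parallel arrays
    ``(pos_bp, pos_cm)`` sorted by position.
    """

    meiosis_id: str
    dosage: int
    crossovers: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dosage not in (0, 1, 2):
            raise ValueError(f"dosage must be 0, 1 or 2, got {self.dosage}")
        for chrom, (bp, cm) in self.crossovers.items():
            bp = np.asarray(bp, dtype=np.int64)
            cm = np.asarray(cm, dtype=float)
            if len(bp) != len(cm):
                raise ValueError(f"{self.meiosis_id}/{chrom}: bp/cM arrays differ in length")
            if len(bp) > 1 and np.any(np.diff(bp) <= 0):
                raise ValueError(f"{self.meiosis_id}/{chrom}: positions must be strictly increasing")
            self.crossovers[chrom] = (bp, cm)

    def n_crossovers(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self.crossovers.get(chrom, ((), ()))[0])
        return sum(len(bp) for bp, _ in self.crossovers.values())


@dataclass
class CarrierEffectSpec:
    """How the focal allele perturbs crossover formation in the generator.

    ``params_by_dosage`` gives the Stahl parameters used for carriers of
    0, 1 and 2 copies.  ``distal_shift_intercept`` / ``distal_shift_slope``
    define a per-allele map distortion strength that is linear in
    chromosome length (Mb): ``theta_c = a + b * l_c``, clipped at 0.
    The distortion is a monotone warp of the genetic axis toward the
    chromosome ends that preserves the endpoints and hence the total map
    length; positive ``theta`` moves crossovers closer to the telomeres.
    """

    params_by_dosage: dict[int, StahlParams]
    distal_shift_intercept: float = 0.0
    distal_shift_slope: float = 0.0  # per Mb

    def __post_init__(self) -> None:
        for d in (0, 1, 2):
            if d not in self.params_by_dosage:
                raise ValueError(f"params_by_dosage missing dosage {d}")

    @classmethod
    def additive(
        cls,
        noncarrier: StahlParams,
        carrier: StahlParams,
        distal_shift_intercept: float = 0.0,
        distal_shift_slope: float = 0.0,
    ) -> "CarrierEffectSpec":
        """Additive dosage model: heterozygotes get the carrier estimate
        (one copy), homozygotes twice the per-allele displacement."""
        d_nu = carrier.nu - noncarrier.nu
        d_p = carrier.p - noncarrier.p
        by_dosage = {
            0: noncarrier,
            1: carrier,
            2: StahlParams(
                nu=max(noncarrier.nu + 2 * d_nu, 1e-3),
                p=min(max(noncarrier.p + 2 * d_p, 0.0), 1.0),
            ),
        }
        return cls(by_dosage, distal_shift_intercept, distal_shift_slope)

    @classmethod
    def null(cls, params: StahlParams) -> "CarrierEffectSpec":
        """No carrier effect: identical parameters at every dosage."""
        return cls({0: params, 1: params, 2: params})

    def shift_strength(self, dosage: int, length_mb: float) -> float:
        theta = self.distal_shift_intercept + self.distal_shift_slope * length_mb
        return max(dosage * theta, 0.0)


def simulate_stahl_process(
    params: StahlParams, L: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw sorted crossover positions (Morgans) on ``[0, L]``.

    Union of the 1/2-thinned stationary gamma renewal pathway (shape
    ``nu``, rate ``2 nu (1-p)`` per Morgan) and the Poisson escape
    pathway (intensity ``p`` per Morgan).
    """
    if not L > 0:
        raise ValueError(f"chromosome genetic length must be positive, got {L}")
    nu, p = params.nu, params.p

    points: list[np.ndarray] = []
    if p < 1.0:
        rate = 2.0 * nu * (1.0 - p)  # chiasma renewal rate per Morgan
        mean_gap = nu / rate  # = 1 / (2 (1 - p))
        start = -BURNIN_GAPS * mean_gap
        # draw gamma gaps in blocks until the chain passes L
        expect = (L - start) / mean_gap
        block = max(int(expect + 6.0 * np.sqrt(expect)) + 4, 16)
        pos = start
        chiasmata = []
        while pos <= L:
            gaps = rng.gamma(shape=nu, scale=1.0 / rate, size=block)
            cum = pos + np.cumsum(gaps)
            chiasmata.append(cum)
            pos = cum[-1]
        chia = np.concatenate(chiasmata)
        chia = chia[(chia >= 0.0) & (chia <= L)]
        keep = rng.random(len(chia)) < 0.5  # chromatid thinning
        points.append(chia[keep])
    if p > 0.0:
        n_escape = rng.poisson(p * L)
        points.append(rng.uniform(0.0, L, size=n_escape))
    xs = np.concatenate(points) if points else np.empty(0)
    xs.sort()
    return xs


def _distal_warp(u: np.ndarray, theta: float) -> np.ndarray:
    """Monotone warp of [0, 1] pushing mass toward 0 and 1.

    Power family on the centred coordinate ``t = 2u - 1``:
    ``t -> sign(t) |t| ** (1 / (1 + theta))``.  ``theta = 0`` is the
    identity; endpoints and the midpoint are fixed for all ``theta``.
    """
    if theta == 0.0:
        return u
    t = 2.0 * np.asarray(u, dtype=float) - 1.0
    warped = np.sign(t) * np.abs(t) ** (1.0 / (1.0 + theta))
    return (warped + 1.0) / 2.0


def simulate_meiosis(
    genome: GenomeModel,
    spec: CarrierEffectSpec,
    dosage: int,
    rng: np.random.Generator,
    meiosis_id: str = "m0",
) -> MeiosisRecord:
    """Simulate one meiosis: per chromosome, draw crossovers under the
    dosage-specific Stahl parameters on the (possibly distorted) genetic
    map, then place them on physical coordinates."""
    params = spec.params_by_dosage[dosage]
    crossovers: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in genome:
        L = chrom.genetic_length_morgans
        xs = simulate_stahl_process(params, L, rng)
        if len(xs) == 0:
            continue
        theta = spec.shift_strength(dosage, chrom.length_mb)
        if theta > 0.0:
            xs = np.sort(_distal_warp(xs / L, theta) * L)
        pos_cm = xs * 100.0
        pos_bp = np.asarray(chrom.gen_to_phys(pos_cm), dtype=float)
        pos_bp = np.round(pos_bp).astype(np.int64)
        # collapse bp ties created by rounding (keeps positions strictly sorted)
        keep = np.concatenate(([True], np.diff(pos_bp) > 0))
        crossovers[chrom.name] = (pos_bp[keep], pos_cm[keep])
    return MeiosisRecord(meiosis_id=meiosis_id, dosage=dosage, crossovers=crossovers)


def simulate_recombination_cohort(
    genome: GenomeModel,
    spec: CarrierEffectSpec,
    n_meioses: int,
    carrier_frequency: float,
    seed: int,
) -> list[MeiosisRecord]:
    """Simulate a cohort of meioses.

    Parent dosages are drawn Binomial(2, ``carrier_frequency``) under
    Hardy-Weinberg equilibrium.  The output is deterministic given
    ``seed``.
    """
    if not 0.0 <= carrier_frequency <= 1.0:
        raise ValueError("carrier_frequency must lie in [0, 1]")
    if n_meioses < 1:
        raise ValueError("n_meioses must be >= 1")
    rng = np.random.default_rng(seed)
    dosages = rng.binomial(2, carrier_frequency, size=n_meioses)
    width = len(str(n_meioses - 1))
    return [
        simulate_meiosis(genome, spec, int(d), rng, meiosis_id=f"m{idx:0{width}d}")
        for idx, d in enumerate(dosages)
    ]


# -- case/control cohorts -----------------------------------------------------


def _calibrate_intercept(freq: float, log_or: float, case_fraction: float) -> float:
    """Solve for the logistic intercept giving the requested marginal
    case fraction under HWE genotype frequencies."""
    if not 0.0 < case_fraction < 1.0:
        raise ValueError(f"case fraction must lie in (0, 1), got {case_fraction}")
    probs = np.array([(1 - freq) ** 2, 2 * freq * (1 - freq), freq**2])
    gs = np.array([0.0, 1.0, 2.0])

    def gap(alpha: float) -> float:
        return float(np.sum(probs * expit(alpha + gs * log_or))) - case_fraction

    return brentq(gap, -40.0, 40.0, xtol=1e-12)


def simulate_case_control_cohorts(
    cohort_sizes: list[tuple[int, int]],
    allele_freqs: list[float],
    true_or: float,
    seed: int,
) -> pd.DataFrame:
    """Simulate case/control cohorts sharing one per-allele odds ratio.

    Each cohort ``c`` has ``(n_cases, n_controls)`` targets and its own
    risk-allele frequency.  Genotypes are Binomial(2, freq); case status
    is Bernoulli with ``logit P(case) = alpha_c + dosage * ln(true_or)``,
    where ``alpha_c`` is calibrated by 1-D root finding so the expected
    case fraction matches the target.  Returns a tidy table with columns
    ``id, dosage, status, cohort``.
    """
    if not true_or > 0:
        raise ValueError("true_or must be positive")
    if len(cohort_sizes) != len(allele_freqs):
        raise ValueError("cohort_sizes and allele_freqs must have equal length")
    log_or = float(np.log(true_or))
    rng = np.random.default_rng(seed)
    frames = []
    for c, ((n_cases, n_controls), freq) in enumerate(zip(cohort_sizes, allele_freqs)):
        if not 0.0 < freq < 1.0:
            raise ValueError(f"allele frequency must lie in (0, 1), got {freq}")
        n = n_cases + n_controls
        alpha = _calibrate_intercept(freq, log_or, n_cases / n)
        dosage = rng.binomial(2, freq, size=n)
        status = (rng.random(n) < expit(alpha + dosage * log_or)).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "id": [f"c{c}_{i}" for i in range(n)],
                    "dosage": dosage,
                    "status": status,
                    "cohort": f"cohort{c}",
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# -- synthetic genomes --------------------------------------------------------


def uniform_rate_genome(
    genetic_lengths_morgans: list[float],
    mb_per_morgan: float = 100.0,
    names: list[str] | None = None,
) -> GenomeModel:
    """Minimal genome with a uniform recombination rate per chromosome.

    Convenient for interference studies where only genetic lengths
    matter; physical lengths follow from ``mb_per_morgan``.
    """
    chroms = []
    for i, L in enumerate(genetic_lengths_morgans):
        name = names[i] if names else f"chr{i + 1}"
        length_bp = int(round(L * mb_per_morgan * 1e6))
        anchors = np.array([[0.0, 0.0], [length_bp, L * 100.0]])
        chroms.append(ChromosomeModel(name=name, physical_length=length_bp, map_anchors=anchors))
    return GenomeModel(chroms)


def synthetic_genome(
    n_chromosomes: int = 6,
    physical_lengths_mb: list[float] | None = None,
    genetic_lengths_cm: list[float] | None = None,
    seed: int = 0,
    n_map_segments: int = 40,
    hot_segment_fraction: float = 0.05,
    hot_fold: float = 20.0,
    track_bin_bp: int = 200_000,
) -> GenomeModel:
    """Build a randomized but reproducible genome for end-to-end runs.

    Each chromosome gets a piecewise-linear genetic map whose segment
    rates vary lognormally around the chromosome mean, with a small
    fraction of hot segments at ``hot_fold`` times the mean rate
    (so hotspot calling has something to find); a GC track fluctuating
    around the genome-typical 0.41; and a smooth replication-timing
    track.  Fully determined by ``seed``.
    """
    rng = np.random.default_rng(seed)
    if physical_lengths_mb is None:
        # roughly human-like spread, largest ~4x the smallest
        physical_lengths_mb = list(np.linspace(220.0, 55.0, n_chromosomes))
    if genetic_lengths_cm is None:
        # female-map-like rate ~1.5 cM/Mb with extra map on small chromosomes
        genetic_lengths_cm = [1.5 * l + 20.0 for l in physical_lengths_mb]
    chroms = []
    for i, (l_mb, g_cm) in enumerate(zip(physical_lengths_mb, genetic_lengths_cm)):
        length_bp = int(round(l_mb * 1e6))
        edges = np.round(np.linspace(0, length_bp, n_map_segments + 1)).astype(np.int64)
        rates = rng.lognormal(mean=0.0, sigma=0.5, size=n_map_segments)
        hot = rng.random(n_map_segments) < hot_segment_fraction
        rates[hot] *= hot_fold
        seg_cm = rates * np.diff(edges)
        seg_cm *= g_cm / seg_cm.sum()
        anchors = np.column_stack([edges, np.concatenate([[0.0], np.cumsum(seg_cm)])])
        nb = max(int(np.ceil(length_bp / track_bin_bp)), 1)
        starts = np.arange(nb, dtype=np.int64) * track_bin_bp
        ends = np.minimum(starts + track_bin_bp, length_bp)
        gc = np.clip(0.41 + 0.05 * rng.standard_normal(nb), 0.25, 0.65)
        rt_raw = np.cumsum(rng.standard_normal(nb))
        rt = (rt_raw - rt_raw.mean()) / (rt_raw.std() + 1e-12)
        chroms.append(
            ChromosomeModel(
                name=f"chr{i + 1}",
                physical_length=length_bp,
                map_anchors=anchors,
                gc_track=BinnedTrack(starts, ends, gc),
                rt_track=BinnedTrack(starts, ends, rt),
            )
        )
    genome = GenomeModel(chroms)
    for chrom in genome:
        hotspot_mask(chrom, genome)
    return genome
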