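"""End-to-end orchestration: simulate -> phenotypes -> association ->
interference -> meta, all reproducible from one config and one seed.

Every output TSV starts with a provenance comment line recording the
package version, the seed and a hash of the config; the run manifest
lists every artifact with its SHA-256 checksum, so two runs with the
same (config, seed) produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from . import __version__
from .association import effects_to_frame, length_interaction, per_chromosome_effects
from .genome import GenomeModel, load_genome, write_bed_intervals
from .interference import carrier_lrt, fit_stahl, records_from_meioses
from .io import (
    write_cohort_table,
    write_crossovers,
    write_meiosis_index,
    write_sumstats,
)
from .meta import cohort_summaries, ivw_meta
from .phenotypes import add_rank_normalized, compute_phenotypes
from .simulate import (
    CarrierEffectSpec,
    StahlParams,
    simulate_case_control_cohorts,
    simulate_recombination_cohort,
    synthetic_genome,
)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run."""

    seed: int
    out_dir: str
    # genome: file paths or synthetic parameters
    genome_files: dict | None = None  # chrom_sizes, genetic_map, [hotspots, gc, rt]
    genome_synthetic: dict = field(
        default_factory=lambda: {"n_chromosomes": 6, "seed": 0}
    )
    # simulation
    n_meioses: int = 2000
    carrier_frequency: float = 0.0125
    noncarrier_params: dict = field(default_factory=lambda: {"nu": 6.61, "p": 0.039})
    carrier_params: dict = field(default_factory=lambda: {"nu": 5.97, "p": 0.045})
    distal_shift_intercept: float = 0.0
    distal_shift_slope: float = 0.0
    # analysis toggles
    phenotypes: list[str] = field(default_factory=lambda: ["RR", "RH", "TD", "GC", "RT"])
    per_chromosome: bool = True
    run_interference: bool = True
    run_meta: bool = True
    # meta-analysis spec
    meta_cohort_sizes: list[list[int]] = field(
        default_factory=lambda: [[2500, 10000], [2500, 10000]]
    )
    meta_allele_freqs: list[float] = field(default_factory=lambda: [0.005, 0.01])
    meta_true_or: float = 1.22

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.genome_files is not None:
            for key in ("chrom_sizes", "genetic_map"):
                if key not in self.genome_files:
                    raise ValueError(f"genome_files must provide {key!r}")
                if not Path(self.genome_files[key]).exists():
                    raise ValueError(f"genome file not found: {self.genome_files[key]}")
        if not 0.0 <= self.carrier_frequency <= 1.0:
            raise ValueError("carrier_frequency must lie in [0, 1]")
        StahlParams(**self.noncarrier_params)
        StahlParams(**self.carrier_params)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ValueError(f"invalid config {path}: {exc}") from None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _build_genome(config: RunConfig) -> GenomeModel:
    if config.genome_files is not None:
        return load_genome(
            config.genome_files["chrom_sizes"],
            config.genome_files["genetic_map"],
            config.genome_files.get("hotspots"),
            config.genome_files.get("gc_track"),
            config.genome_files.get("rt_track"),
        )
    return synthetic_genome(**config.genome_synthetic)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = f"# recombkit {__version__} seed={config.seed} config={config.config_hash()}"
    artifacts: list[Path] = []

    genome = _build_genome(config)
    hotspot_path = out / "hotspots.bed"
    write_bed_intervals(genome, hotspot_path)
    artifacts.append(hotspot_path)

    spec = CarrierEffectSpec.additive(
        StahlParams(**config.noncarrier_params),
        StahlParams(**config.carrier_params),
        distal_shift_intercept=config.distal_shift_intercept,
        distal_shift_slope=config.distal_shift_slope,
    )
    logger.info("simulating %d meioses", config.n_meioses)
    meioses = simulate_recombination_cohort(
        genome, spec, config.n_meioses, config.carrier_frequency, seed=config.seed
    )
    xo_path = out / "crossovers.tsv"
    write_crossovers(meioses, xo_path, comment=prov)
    idx_path = out / "meioses.tsv"
    write_meiosis_index(meioses, idx_path, comment=prov)
    artifacts += [xo_path, idx_path]

    table = add_rank_normalized(compute_phenotypes(meioses, genome))
    pheno_path = out / "phenotypes.tsv"
    with open(pheno_path, "w") as fh:
        fh.write(prov + "\n")
        table.reset_index().to_csv(fh, sep="\t", index=False, float_format="%.6g")
    artifacts.append(pheno_path)

    if config.per_chromosome:
        eff_frames = []
        inter_rows = []
        for pheno in config.phenotypes:
            effects = per_chromosome_effects(table, genome, pheno)
            eff_frames.append(effects_to_frame(effects))
            if len(effects) >= 3 and all(e.se > 0 for e in effects):
                ifit = length_interaction(effects)
                inter_rows.append(
                    {
                        "phenotype": pheno,
                        "slope_per_mb": ifit.slope,
                        "se": ifit.se,
                        "p": ifit.p,
                        "intercept": ifit.intercept,
                    }
                )
        eff_path = out / "per_chromosome_effects.tsv"
        with open(eff_path, "w") as fh:
            fh.write(prov + "\n")
            pd.concat(eff_frames, ignore_index=True).to_csv(
                fh, sep="\t", index=False, float_format="%.6g"
            )
        artifacts.append(eff_path)
        if inter_rows:
            inter_path = out / "length_interaction.tsv"
            with open(inter_path, "w") as fh:
                fh.write(prov + "\n")
                pd.DataFrame(inter_rows).to_csv(fh, sep="\t", index=False, float_format="%.6g")
            artifacts.append(inter_path)

    if config.run_interference:
        carriers = [m for m in meioses if m.dosage > 0]
        noncarriers = [m for m in meioses if m.dosage == 0]
        rows = []
        if carriers and noncarriers:
            lrt = carrier_lrt(
                records_from_meioses(carriers, genome),
                records_from_meioses(noncarriers, genome),
            )
            for label, f in (
                ("carrier", lrt.fit_carrier),
                ("noncarrier", lrt.fit_noncarrier),
                ("pooled", lrt.fit_pooled),
            ):
                rows.append(
                    {
                        "group": label,
                        "nu_hat": f.nu_hat,
                        "p_hat": f.p_hat,
                        "loglik": f.loglik,
                        "n_records": f.n_records,
                        "converged": f.converged,
                    }
                )
            lrt_path = out / "interference_lrt.tsv"
            with open(lrt_path, "w") as fh:
                fh.write(prov + "\n")
                pd.DataFrame(
                    [{"chi2": lrt.chi2, "df": lrt.df, "p": lrt.p_value}]
                ).to_csv(fh, sep="\t", index=False, float_format="%.6g")
            artifacts.append(lrt_path)
        else:
            f = fit_stahl(records_from_meioses(meioses, genome))
            rows.append(
                {
                    "group": "all",
                    "nu_hat": f.nu_hat,
                    "p_hat": f.p_hat,
                    "loglik": f.loglik,
                    "n_records": f.n_records,
                    "converged": f.converged,
                }
            )
        fit_path = out / "interference_fits.tsv"
        with open(fit_path, "w") as fh:
            fh.write(prov + "\n")
            pd.DataFrame(rows).to_csv(fh, sep="\t", index=False, float_format="%.6g")
        artifacts.append(fit_path)

    if config.run_meta:
        tables = simulate_case_control_cohorts(
            [tuple(x) for x in config.meta_cohort_sizes],
            config.meta_allele_freqs,
            config.meta_true_or,
            seed=config.seed + 1,
        )
        cc_path = out / "cohorts.tsv"
        write_cohort_table(tables, cc_path, comment=prov)
        artifacts.append(cc_path)
        summaries = cohort_summaries(tables)
        sumstats = pd.DataFrame(
            {
                "chrom": "chr19",
                "pos": 12175438,
                "ref": "C",
                "alt": "T",
                "beta": [s.beta for s in summaries],
                "se": [s.se for s in summaries],
                "p": 0.0,
                "af": [s.af for s in summaries],
                "n_cases": [s.n_cases for s in summaries],
                "n_controls": [s.n_controls for s in summaries],
                "cohort": [s.cohort for s in summaries],
            }
        )
        sumstats["p"] = 2 * norm.sf(np.abs(sumstats.beta / sumstats.se))
        ss_path = out / "sumstats.tsv"
        write_sumstats(sumstats, ss_path, comment=prov)
        artifacts.append(ss_path)
        m = ivw_meta(summaries)
        meta_path = out / "meta.tsv"
        with open(meta_path, "w") as fh:
            fh.write(prov + "\n")
            pd.DataFrame(
                [
                    {
                        "beta": m.beta,
                        "se": m.se,
                        "p": m.p,
                        "OR": m.or_,
                        "ci_low": m.ci_low,
                        "ci_high": m.ci_high,
                        "Q": m.q,
                        "p_het": m.p_het,
                        "k": m.k_studies,
                    }
                ]
            ).to_csv(fh, sep="\t", index=False, float_format="%.6g")
        artifacts.append(meta_path)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
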