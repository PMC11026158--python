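"""TSV dialects for crossovers, cohort tables and summary statistics.

All files are tab-separated with a header row; lines starting with ``#``
are provenance/comment lines and are ignored on read (the first one is
returned to the caller so a round trip can preserve it).  Crossover
physical positions are 0-based; summary-statistics positions are 1-based
as is conventional for GWAS summary files.  Writers use fixed numeric
formats so that write -> read -> write is byte-identical.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .simulate import MeiosisRecord

__all__ = [
    "read_crossovers",
    "write_crossovers",
    "read_meiosis_index",
    "write_meiosis_index",
    "read_cohort_table",
    "write_cohort_table",
    "read_sumstats",
    "write_sumstats",
]

_XO_COLUMNS = ["meiosis_id", "dosage", "chrom", "pos_bp", "pos_cM"]
_SUMSTAT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "beta", "se", "p", "af", "n_cases", "n_controls", "cohort",
]
_COHORT_COLUMNS = ["id", "dosage", "status", "cohort"]


class TsvFormatError(ValueError):
    """Malformed input file; message carries the 1-based line number."""


def _read_tsv(path, required: list[str]) -> tuple[pd.DataFrame, str | None, list[int]]:
    """Read a headered TSV, returning (frame, first comment line, data
    line numbers).  Column order in the file is free; the header names
    drive parsing."""
    comment = None
    header: list[str] | None = None
    rows: list[list[str]] = []
    line_numbers: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if comment is None:
                    comment = line
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in required if c not in header]
                if missing:
                    raise TsvFormatError(
                        f"{path}: missing required column(s) {missing} in header"
                    )
                continue
            if len(fields) != len(header):
                raise TsvFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            rows.append(fields)
            line_numbers.append(lineno)
    if header is None:
        raise TsvFormatError(f"{path}: no header line found")
    df = pd.DataFrame(rows, columns=header)
    return df, comment, line_numbers


def read_crossovers(
    path, genome: GenomeModel | None = None, meiosis_index_path=None
) -> tuple[list[MeiosisRecord], str | None]:
    """Read a crossover table into :class:`MeiosisRecord` objects.

    With a genome, every position is validated against the chromosome
    span and errors carry the offending line number.  Returns the
    records and the file's first provenance comment (if any).

    A crossover table cannot represent a meiosis with no crossovers at
    all; passing the companion meiosis-index file restores such records
    (they matter for the interference likelihood).
    """
    df, comment, linenos = _read_tsv(path, _XO_COLUMNS)
    try:
        df["dosage"] = df["dosage"].astype(int)
        df["pos_bp"] = df["pos_bp"].astype(np.int64)
        df["pos_cM"] = df["pos_cM"].astype(float)
    except ValueError as exc:
        raise TsvFormatError(f"{path}: non-numeric field ({exc})") from None
    df["_lineno"] = linenos

    if genome is not None:
        for _, row in df.iterrows():
            if row.chrom not in genome:
                raise TsvFormatError(
                    f"{path}:{row._lineno}: unknown chromosome {row.chrom!r}"
                )
            length = genome[row.chrom].physical_length
            if not 0 <= row.pos_bp < length:
                raise TsvFormatError(
                    f"{path}:{row._lineno}: pos_bp {row.pos_bp} outside "
                    f"[0, {length}) on {row.chrom}"
                )

    records = []
    for mid, sub in df.groupby("meiosis_id", sort=False):
        dosages = sub.dosage.unique()
        if len(dosages) != 1:
            raise TsvFormatError(f"{path}: meiosis {mid!r} has inconsistent dosage values")
        crossovers = {}
        for chrom, cs in sub.groupby("chrom", sort=False):
            bp = cs.pos_bp.to_numpy()
            if np.any(np.diff(bp) <= 0):
                bad = int(cs._lineno.iloc[int(np.argmin(np.diff(bp) > 0)) + 1])
                raise TsvFormatError(
                    f"{path}:{bad}: crossovers not strictly sorted within "
                    f"meiosis {mid!r} on {chrom}"
                )
            crossovers[str(chrom)] = (bp, cs.pos_cM.to_numpy())
        records.append(
            MeiosisRecord(meiosis_id=str(mid), dosage=int(dosages[0]), crossovers=crossovers)
        )

    if meiosis_index_path is not None:
        index, _ = read_meiosis_index(meiosis_index_path)
        seen = {r.meiosis_id for r in records}
        by_id = {r.meiosis_id: r for r in records}
        ordered = []
        for row in index.itertuples(index=False):
            mid = str(row.meiosis_id)
            if mid in seen:
                if by_id[mid].dosage != int(row.dosage):
                    raise TsvFormatError(
                        f"{path}: dosage mismatch with index for meiosis {mid!r}"
                    )
                ordered.append(by_id[mid])
            else:
                ordered.append(MeiosisRecord(meiosis_id=mid, dosage=int(row.dosage)))
        records = ordered
    return records, comment


def read_meiosis_index(path) -> tuple[pd.DataFrame, str | None]:
    df, comment, _ = _read_tsv(path, ["meiosis_id", "dosage"])
    df["dosage"] = df["dosage"].astype(int)
    return df[["meiosis_id", "dosage"]], comment


def write_meiosis_index(records: list[MeiosisRecord], path, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(comment.rstrip("\n") + "\n")
        fh.write("meiosis_id\tdosage\n")
        for rec in records:
            fh.write(f"{rec.meiosis_id}\t{rec.dosage}\n")


def write_crossovers(records: list[MeiosisRecord], path, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(comment.rstrip("\n") + "\n")
        fh.write("\t".join(_XO_COLUMNS) + "\n")
        for rec in records:
            for chrom in sorted(rec.crossovers):
                bp, cm = rec.crossovers[chrom]
                for b, c in zip(bp, cm):
                    fh.write(f"{rec.meiosis_id}\t{rec.dosage}\t{chrom}\t{int(b)}\t{c:.6f}\n")


def read_cohort_table(path) -> tuple[pd.DataFrame, str | None]:
    df, comment, _ = _read_tsv(path, _COHORT_COLUMNS)
    df["dosage"] = df["dosage"].astype(int)
    df["status"] = df["status"].astype(int)
    return df[_COHORT_COLUMNS], comment


def write_cohort_table(df: pd.DataFrame, path, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(comment.rstrip("\n") + "\n")
        fh.write("\t".join(_COHORT_COLUMNS) + "\n")
        for row in df[_COHORT_COLUMNS].itertuples(index=False):
            fh.write(f"{row.id}\t{row.dosage}\t{row.status}\t{row.cohort}\n")


def read_sumstats(path) -> tuple[pd.DataFrame, str | None]:
    """Summary statistics TSV (positions 1-based)."""
    df, comment, _ = _read_tsv(path, _SUMSTAT_COLUMNS)
    for col in ("pos", "n_cases", "n_controls"):
        df[col] = df[col].astype(np.int64)
    for col in ("beta", "se", "p", "af"):
        df[col] = df[col].astype(float)
    return df[_SUMSTAT_COLUMNS], comment


def write_sumstats(df: pd.DataFrame, path, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(comment.rstrip("\n") + "\n")
        fh.write("# positions are 1-based\n")
        fh.write("\t".join(_SUMSTAT_COLUMNS) + "\n")
        for row in df[_SUMSTAT_COLUMNS].itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.ref}\t{row.alt}\t{row.beta:.6g}\t"
                f"{row.se:.6g}\t{row.p:.6g}\t{row.af:.6g}\t{row.n_cases}\t"
                f"{row.n_controls}\t{row.cohort}\n"
            )
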