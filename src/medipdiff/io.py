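"""Readers and writers for the plain-text formats the pipeline consumes.

All genomic coordinates are 0-based, half-open (BED convention). Interval
tables are plain :class:`pandas.DataFrame` objects with at least the columns
``chrom``, ``start`` and ``end``; BED6 adds ``name``, ``score`` and
``strand``. FASTA parsing goes through Biopython, JASPAR position frequency
matrices through :mod:`Bio.motifs`.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED3_COLUMNS = ["chrom", "start", "end"]
BED6_COLUMNS = BED3_COLUMNS + ["name", "score", "strand"]


class ParseError(ValueError):
    """Raised for malformed input lines; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


def _validate_intervals(df: pd.DataFrame) -> pd.DataFrame:
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise ParseError(
            f"interval with start >= end at record {bad[0] + 1}", int(bad[0]) + 1
        )
    return df


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3/BED6 file into an interval DataFrame."""
    rows = []
    n_fields = 3
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"expected >=3 tab-separated fields, got {len(parts)}", i)
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), *parts[3:6]))
            except ValueError as exc:
                raise ParseError(str(exc), i) from exc
            n_fields = max(n_fields, min(len(parts), 6))
    cols = BED6_COLUMNS[:n_fields]
    df = pd.DataFrame([r[:n_fields] for r in rows], columns=cols)
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce").fillna(0)
    return _validate_intervals(df)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    """Write the BED columns present in ``df`` (BED3 or BED6)."""
    cols = BED6_COLUMNS if set(BED6_COLUMNS) <= set(df.columns) else BED3_COLUMNS
    out = df[cols].copy()
    out["start"] = out["start"].astype(int)
    out["end"] = out["end"].astype(int)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_genome_table(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` table."""
    table: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError("expected two tab-separated fields", i)
            try:
                table[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise ParseError(str(exc), i) from exc
    if not table:
        raise ParseError("empty genome table")
    return table


def write_genome_table(table: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in table.items():
            fh.write(f"{chrom}\t{length}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into ``{name: sequence}`` with upper-cased sequences."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_jaspar_pfms(path: str | Path) -> list:
    """Read JASPAR-format PFMs; returns a list of Bio.motifs motif objects."""
    with open(path) as fh:
        return list(motifs.parse(fh, "jaspar"))


def write_jaspar_pfms(motif_list, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(motifs.write(motif_list, "jaspar"))


SNP_COLUMNS = ["chrom", "pos", "ref", "alt", "maternal_allele", "paternal_allele"]


def read_snp_table(path: str | Path) -> pd.DataFrame:
    """Read the SNP TSV (chrom, pos, ref, alt, maternal/paternal alleles)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SNP_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ParseError(f"SNP table missing columns: {missing}")
    df["pos"] = df["pos"].astype(int)
    bad = df.index[df["ref"] == df["alt"]]
    if len(bad):
        raise ParseError(f"ref == alt at record {bad[0] + 1}", int(bad[0]) + 1)
    return df


def write_snp_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_tsv(df: pd.DataFrame, path: str | Path, provenance: Mapping | None = None) -> None:
    """Write a TSV with optional ``# key=value`` provenance header lines."""
    buf = _io.StringIO()
    if provenance:
        for key, val in provenance.items():
            buf.write(f"# {key}={val}\n")
    df.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
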