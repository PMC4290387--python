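"""Readers and writers for the pipeline's on-disk formats.

All genomic coordinates are 0-based half-open (BED convention) in memory;
1-based inputs are converted at the boundary via the ``one_based`` flag.
Malformed lines are reported with file and line number.  Matrices are
stored gene-major TSV with a header naming individuals.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class FormatError(ValueError):
    pass


def bed_read(path: str | Path, one_based: bool = False) -> pd.DataFrame:
    """Read a BED(+score) file; tolerates 3-6 columns, empty file → empty table."""
    rows = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if one_based:
                start -= 1
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end <= start")
            row = {"chrom": parts[0], "start": start, "end": end}
            if len(parts) > 3:
                row["name"] = parts[3]
            if len(parts) > 4:
                try:
                    row["score"] = float(parts[4])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
            if len(parts) > 5:
                row["strand"] = parts[5]
            rows.append(row)
    if not rows:
        return pd.DataFrame(columns=BED_COLUMNS[:3])
    return pd.DataFrame(rows)


def bed_write(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    out = df[cols].copy()
    out.to_csv(path, sep="\t", header=False, index=False)


def tsv_read(path: str | Path, **kwargs) -> pd.DataFrame:
    """Headered TSV; an empty file yields an empty table, not an error."""
    path = Path(path)
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def tsv_write(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def matrix_write(df: pd.DataFrame, path: str | Path, index_name: str = "gene_id") -> None:
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")


def matrix_read(path: str | Path, index_name: str = "gene_id") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def gene_model_read(path: str | Path) -> pd.DataFrame:
    df = tsv_read(path)
    required = {"gene_id", "chrom", "tss", "strand", "exon_starts", "exon_ends"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing gene-model column(s) {sorted(missing)}")
    return df


def ortholog_read(path: str | Path) -> pd.DataFrame:
    df = tsv_read(path)
    required = {
        "species_a",
        "chrom_a",
        "start_a",
        "end_a",
        "species_b",
        "chrom_b",
        "start_b",
        "end_b",
        "aligned_fraction",
    }
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing ortholog column(s) {sorted(missing)}")
    bad = df[(df["aligned_fraction"] < 0) | (df["aligned_fraction"] > 1)]
    if len(bad):
        raise FormatError(f"{path}: aligned_fraction outside [0, 1]")
    return df


def config_read(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}
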