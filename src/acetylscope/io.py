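"""Readers and writers for the plain-text formats the pipeline exchanges.

BED is 0-based half-open; GFF3 is 1-based closed and converted on the
boundary. Tag libraries are BED6 single-base intervals; the expression
matrix is a TSV (rows = genes, columns = samples) with a two-column
sample -> group sidecar TSV.
"""
from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .models import ExpressionMatrix, GeneModel, TagLibrary

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


class FormatError(ValueError):
    """Malformed record in an input file; message carries the 1-based line number."""


def _read_bed6(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=_BED_COLS,
            dtype={"chrom": str, "name": str, "strand": str},
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=_BED_COLS)
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: malformed BED: {exc}") from exc
    # recover original line numbers (comment lines shift them)
    with open(path) as fh:
        data_lines = [i + 1 for i, line in enumerate(fh) if line.strip() and not line.startswith("#")]
    for col in ("start", "end"):
        nums = pd.to_numeric(df[col], errors="coerce")
        bad = nums.isna()
        if bad.any():
            line = data_lines[int(np.argmax(bad.to_numpy()))]
            raise FormatError(f"{path}: non-integer {col} at line {line}")
        df[col] = nums.astype(np.int64)
    neg = (df["start"] < 0) | (df["end"] < 0)
    if neg.any():
        line = data_lines[int(np.argmax(neg.to_numpy()))]
        raise FormatError(f"{path}: negative coordinate at line {line}")
    rev = df["start"] >= df["end"]
    if rev.any():
        line = data_lines[int(np.argmax(rev.to_numpy()))]
        raise FormatError(f"{path}: start >= end at line {line}")
    badstrand = ~df["strand"].isin(["+", "-"])
    if badstrand.any():
        line = data_lines[int(np.argmax(badstrand.to_numpy()))]
        raise FormatError(f"{path}: strand must be '+' or '-' at line {line}")
    return df


def read_tags(path: str | Path, sample_id: str = "", condition: str = "SS",
              role: str = "IP") -> TagLibrary:
    """Read a single-base BED6 tag library."""
    df = _read_bed6(path)
    tags = pd.DataFrame(
        {"chrom": df["chrom"].astype(str), "pos": df["start"].astype(np.int64),
         "strand": df["strand"].astype(str)}
    )
    return TagLibrary(sample_id=sample_id or Path(path).stem, condition=condition,
                      role=role, tags=tags)


def write_tags(library: TagLibrary, path: str | Path) -> None:
    df = library.tags
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"],
            "end": df["pos"] + 1,
            "name": [f"tag{i}" for i in range(len(df))],
            "score": 0,
            "strand": df["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_annotation_bed(path: str | Path) -> list[GeneModel]:
    df = _read_bed6(path)
    return [
        GeneModel(gene_id=str(r.name), chrom=str(r.chrom), start=int(r.start),
                  end=int(r.end), strand=str(r.strand))
        for r in df.itertuples(index=False)
    ]


def write_annotation_bed(annotation: Sequence[GeneModel], path: str | Path) -> None:
    rows = [
        (g.chrom, g.start, g.end, g.gene_id, 0, g.strand) for g in annotation
    ]
    pd.DataFrame(rows, columns=_BED_COLS).to_csv(path, sep="\t", header=False, index=False)


def read_annotation_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene features from GFF3 (1-based closed -> 0-based half-open)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}: expected 9 GFF3 columns at line {lineno}")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype != "gene":
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gid = attr.get("ID") or attr.get("gene_id")
            if gid is None:
                raise FormatError(f"{path}: gene without ID attribute at line {lineno}")
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}: non-integer coordinate at line {lineno}") from exc
            genes.append(GeneModel(gene_id=gid, chrom=chrom, start=s - 1, end=e, strand=strand))
    return genes


def write_annotation_gff3(annotation: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation:
            fh.write(
                f"{g.chrom}\tacetylscope\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_expression(matrix_path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    gmap = pd.read_csv(groups_path, sep="\t", index_col=0)
    if gmap.shape[1] != 1:
        raise FormatError(f"{groups_path}: expected two columns (sample, group)")
    groups = gmap.iloc[:, 0].astype(str)
    groups.index = groups.index.astype(str)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    return ExpressionMatrix(values=values, groups=groups)


def write_expression(matrix: ExpressionMatrix, matrix_path: str | Path,
                     groups_path: str | Path) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
    matrix.groups.rename("group").to_csv(groups_path, sep="\t", index_label="sample_id")


def write_sites_bed(sites, path: str | Path) -> None:
    """Called binding sites as BED6; score = -log10(p) clipped at 1000."""
    rows = []
    for i, s in enumerate(sites):
        score = 1000.0 if s.enrichment_p <= 1e-300 else min(1000.0, -np.log10(s.enrichment_p))
        rows.append((s.chrom, s.start, s.end, f"site{i}", round(score, 3), "."))
    pd.DataFrame(rows, columns=_BED_COLS).to_csv(path, sep="\t", header=False, index=False)


def write_tsv(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label,
              quoting=csv.QUOTE_MINIMAL)
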