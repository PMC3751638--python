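"""Domain containers shared across the pipeline.

Coordinates are 0-based half-open throughout (BED native); GFF3 is
converted at the I/O boundary only.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("SS", "SM", "MS", "MM")
ROLES = ("IP", "input")


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to what tag quantification needs: span, strand, TSS.

    The TSS is the 5' end of the gene body: ``start`` on the + strand,
    ``end - 1`` on the - strand. The promoter window used for assignment
    is TSS-centred, so "nearest promoter" equals "nearest TSS".
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def promoter(self, halfwidth: int) -> tuple[int, int]:
        """TSS-centred window [tss - halfwidth, tss + halfwidth), clipped at 0."""
        if halfwidth <= 0:
            raise ValueError("promoter halfwidth must be positive")
        return max(0, self.tss - halfwidth), self.tss + halfwidth


@dataclass
class TagLibrary:
    """One sample's single-position ChIP tags.

    ``tags`` is a DataFrame with columns chrom (str), pos (int, 0-based),
    strand ('+'/'-'). ``total_count`` is the library size used for
    tags-per-million normalization.
    """

    sample_id: str
    condition: str
    role: str
    tags: pd.DataFrame

    def __post_init__(self) -> None:
        if self.condition not in GROUPS:
            raise ValueError(f"condition must be one of {GROUPS}, got {self.condition!r}")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        required = {"chrom", "pos", "strand"}
        if not required.issubset(self.tags.columns):
            raise ValueError(f"tags frame needs columns {sorted(required)}")
        if len(self.tags) and (self.tags["pos"] < 0).any():
            bad = int(np.argmax(self.tags["pos"].to_numpy() < 0))
            raise ValueError(f"negative tag position at record {bad}")

    @property
    def total_count(self) -> int:
        return len(self.tags)


@dataclass(frozen=True)
class BindingSite:
    """A merged run of significant windows where IP exceeds the input-scaled
    expectation."""

    chrom: str
    start: int
    end: int
    ip_tags: float
    expected_input_tags: float
    enrichment_p: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("site start must be < end")
        if self.ip_tags < 0:
            raise ValueError("ip_tags must be non-negative")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class TssProfile:
    """Aggregate tag density around TSSs (metagene profile).

    ``bin_left`` holds the signed distance of each bin's left edge
    (upstream negative); ``density`` is tags per million library tags.
    """

    flank: int
    binwidth: int
    bin_left: np.ndarray
    counts: np.ndarray
    density: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.bin_left)


@dataclass
class ExpressionMatrix:
    """Genes x samples positive intensities with a sample -> group design."""

    values: pd.DataFrame  # rows=genes, cols=samples, linear scale
    groups: pd.Series  # index=sample_id, values in GROUPS

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("expression intensities must be strictly positive")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")
        bad = set(self.groups) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def group_mean(self, group: str) -> pd.Series:
        """Per-gene mean linear intensity over a group's samples."""
        cols = self.samples_in(group)
        if not cols:
            raise ValueError(f"no samples in group {group!r}")
        return self.values[cols].mean(axis=1)


@dataclass(frozen=True)
class BinSummary:
    """One bin of ``bin_size`` genes of adjacent expression Z score."""

    bin_index: int
    n_genes: int
    mean_z: float
    mean_norm_tags: float
    partial: bool


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n_bins: int

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared outside [0, 1]")


#: binding_status values for a gene not detected on the ChIP platform / unchanged
ABSENT = "absent"
NC = "NC"


@dataclass(frozen=True)
class ConcordanceRecord:
    """One differentially expressed gene's binding outcome (a Table row).

    ``binding_status`` is 'increased', 'decreased', 'NC', or 'absent';
    ``binding_fold`` carries the signed fold when numeric, else NaN.
    """

    gene_id: str
    expr_signed_fc: float
    expr_direction: str  # 'up' | 'down'
    binding_status: str
    binding_fold: float = float("nan")

    def __post_init__(self) -> None:
        if self.expr_direction not in ("up", "down"):
            raise ValueError("expr_direction must be 'up' or 'down'")
        if (self.expr_direction == "up") != (self.expr_signed_fc > 0):
            raise ValueError("expr_direction inconsistent with sign of expr_signed_fc")
        if self.binding_status not in ("increased", "decreased", NC, ABSENT):
            raise ValueError(f"bad binding_status {self.binding_status!r}")


def signed_fold(ratio: float | np.ndarray) -> float | np.ndarray:
    """Convert a linear ratio to the signed convention: ratio if >= 1,
    else -1/ratio (so a 1.85-fold decrease prints as -1.85)."""
    arr = np.asarray(ratio, dtype=float)
    if (arr <= 0).any():
        raise ValueError("ratio must be positive")
    out = np.where(arr >= 1.0, arr, -1.0 / arr)
    return float(out) if np.isscalar(ratio) or out.ndim == 0 else out


def unsigned_ratio(signed: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`signed_fold`."""
    arr = np.asarray(signed, dtype=float)
    if (np.abs(arr) < 1).any():
        raise ValueError("|signed fold| must be >= 1")
    out = np.where(arr >= 0, arr, -1.0 / arr)
    return float(out) if np.isscalar(signed) or out.ndim == 0 else out


def tss_arrays(annotation: Sequence[GeneModel]) -> dict[str, tuple[np.ndarray, list[str], np.ndarray]]:
    """Per-chromosome (sorted unique TSS array, representative gene ids, strands).

    Genes are ordered by (tss, gene_id); when several genes share a TSS the
    lexicographically smallest gene_id represents that coordinate, which
    realises the documented tie-break.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: dict[str, tuple[np.ndarray, list[str], np.ndarray]] = {}
    for chrom, genes in by_chrom.items():
        genes = sorted(genes, key=lambda g: (g.tss, g.gene_id))
        tss, ids, strands = [], [], []
        for g in genes:
            if tss and g.tss == tss[-1]:
                continue  # first (lex-smallest) gene at this TSS represents it
            tss.append(g.tss)
            ids.append(g.gene_id)
            strands.append(1 if g.strand == "+" else -1)
        out[chrom] = (np.asarray(tss, dtype=np.int64), ids, np.asarray(strands, dtype=np.int8))
    return out


def nearest_tss_index(tss_sorted: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Index of the nearest TSS for each position; equidistant ties go to
    the smaller TSS coordinate."""
    idx = np.searchsorted(tss_sorted, positions)
    left = np.clip(idx - 1, 0, len(tss_sorted) - 1)
    right = np.clip(idx, 0, len(tss_sorted) - 1)
    d_left = np.abs(positions - tss_sorted[left])
    d_right = np.abs(positions - tss_sorted[right])
    # tie (d_left == d_right) resolves to the left, i.e. smaller coordinate
    return np.where(d_right < d_left, right, left)
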