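"""Expression-binding integration: 100-gene binned Z-score regression,
input-corrected binding fold change, and Up/Down x
increased/decreased/NC/absent concordance tables.

The binned regression averages out per-gene tag noise: genes are sorted
by expression Z score, grouped into runs of ``bin_size`` (default 100),
and the per-bin mean normalized tag count is regressed on the per-bin
mean Z by ordinary least squares. A positive slope with high R² indicates
that promoter acetylation tracks expression.
"""
from __future__ import annotations

from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import ABSENT, NC, BinSummary, ConcordanceRecord, RegressionResult, signed_fold
from .tags import overlap_partition


def bin_genes(
    z_by_gene: pd.Series,
    norm_tags_by_gene: pd.Series,
    bin_size: int = 100,
) -> list[BinSummary]:
    """Sort genes ascending by Z (ties by gene_id) and form consecutive
    bins of ``bin_size``; a trailing remainder becomes a final bin flagged
    partial. Both inputs must cover the same gene universe."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if len(z_by_gene) == 0:
        raise ValueError("empty input")
    z_set, t_set = set(z_by_gene.index), set(norm_tags_by_gene.index)
    if z_set != t_set:
        only_z = sorted(z_set - t_set)[:5]
        only_t = sorted(t_set - z_set)[:5]
        raise ValueError(
            f"gene universes differ: only in Z e.g. {only_z}; only in tags e.g. {only_t}"
        )
    # stable sort by gene_id first, then by z => ordering by (z, gene_id)
    order = pd.DataFrame({"z": z_by_gene}).sort_index(kind="mergesort")
    order = order.sort_values("z", kind="mergesort")
    idx = order.index
    tags = norm_tags_by_gene.loc[idx]
    bins: list[BinSummary] = []
    for b, lo in enumerate(range(0, len(idx), bin_size)):
        zc = order["z"].iloc[lo : lo + bin_size]
        tc = tags.iloc[lo : lo + bin_size]
        bins.append(
            BinSummary(
                bin_index=b,
                n_genes=len(zc),
                mean_z=float(zc.mean()),
                mean_norm_tags=float(tc.mean()),
                partial=len(zc) < bin_size,
            )
        )
    return bins


def bin_regression(bins: Sequence[BinSummary], include_partial: bool = False) -> RegressionResult:
    """OLS of mean normalized tag count on mean Z over the bins.

    Partial (remainder) bins are excluded by default. A constant response
    gives slope 0 and, by convention, R² = 0.
    """
    usable = [b for b in bins if include_partial or not b.partial]
    if len(usable) < 3:
        raise ValueError(f"need >= 3 usable bins, got {len(usable)}")
    x = np.array([b.mean_z for b in usable])
    y = np.array([b.mean_norm_tags for b in usable])
    if np.ptp(x) == 0:
        raise ValueError("mean_z is constant across bins; regression undefined")
    if np.ptp(y) == 0:
        return RegressionResult(slope=0.0, intercept=float(y[0]), r_squared=0.0,
                                n_bins=len(usable))
    res = stats.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=float(res.rvalue**2), n_bins=len(usable))


def binding_fold_change(
    ip_a: pd.Series,
    input_a: pd.Series,
    ip_b: pd.Series,
    input_b: pd.Series,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-gene signed binding fold of condition B over A after input
    correction: ((ip_B + c)/(input_B + c)) / ((ip_A + c)/(input_A + c)),
    signed-fold converted. The pseudocount c guards zero counts."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    genes = ip_a.index
    input_a, ip_b, input_b = (s.reindex(genes) for s in (input_a, ip_b, input_b))
    if input_a.isna().any() or ip_b.isna().any() or input_b.isna().any():
        raise ValueError("per-gene count series must share a gene universe")
    enr_a = (ip_a + pseudocount) / (input_a + pseudocount)
    enr_b = (ip_b + pseudocount) / (input_b + pseudocount)
    ratio = (enr_b / enr_a).to_numpy(dtype=float)
    return pd.Series(signed_fold(ratio), index=genes, name="binding_fold")


def classify_concordance(
    de_table: pd.DataFrame,
    binding_fold_by_gene: Mapping[str, float] | pd.Series,
    binding_detected: set[str],
    nc_threshold: float = 1.4,
) -> list[ConcordanceRecord]:
    """Attach a binding status to every called DE gene.

    absent: gene not detected on the ChIP platform; NC: detected but
    |signed binding fold| < nc_threshold; else increased/decreased by the
    fold's sign. A gene in the detected set but missing from the fold map
    is treated as absent (documented edge case).
    """
    if nc_threshold < 1:
        raise ValueError("nc_threshold must be >= 1 (signed-fold units)")
    fold_map = dict(pd.Series(binding_fold_by_gene)) if len(binding_fold_by_gene) else {}
    records: list[ConcordanceRecord] = []
    for gene, row in de_table.iterrows():
        if row["call"] not in ("up", "down"):
            continue
        if gene not in binding_detected or gene not in fold_map:
            status, fold = ABSENT, float("nan")
        else:
            fold = float(fold_map[gene])
            if abs(fold) < nc_threshold:
                status = NC
            else:
                status = "increased" if fold > 0 else "decreased"
        records.append(
            ConcordanceRecord(
                gene_id=str(gene),
                expr_signed_fc=float(row["signed_fc"]),
                expr_direction=str(row["call"]),
                binding_status=status,
                binding_fold=fold,
            )
        )
    return records


def concordance_counts(records: Iterable[ConcordanceRecord]) -> tuple[pd.DataFrame, dict[str, int]]:
    """2x4 contingency table (expression direction x binding status) plus
    both-platform totals (records whose status is not absent)."""
    statuses = ["increased", "decreased", NC, ABSENT]
    table = pd.DataFrame(0, index=["up", "down"], columns=statuses, dtype=int)
    for r in records:
        table.loc[r.expr_direction, r.binding_status] += 1
    totals = {
        d: int(table.loc[d, ["increased", "decreased", NC]].sum()) for d in ("up", "down")
    }
    return table, totals


def de_set_overlap(de_tables: Mapping[str, pd.DataFrame], reference: str | None = None):
    """Venn partition of the called (up or down) gene sets per contrast."""
    if len(de_tables) < 2:
        raise ValueError("need at least two DE tables")
    sets = {
        name: set(t.index[t["call"] != "null"]) for name, t in de_tables.items()
    }
    return overlap_partition(sets, reference=reference)


# ---------------------------------------------------------------------------
# Packaged fixtures transcribing the published concordance tables


def load_table_fixture(which: str) -> pd.DataFrame:
    """Load a packaged concordance-table fixture ('table1' or 'table2').

    Columns: symbol, fc (signed expression fold), binding_code (a signed
    fold as text, 'NC', or '*' for not detected on the ChIP platform).
    Duplicate symbols (probe-level duplicates) get a '.2', '.3', ...
    suffix in the returned gene_id index; the symbol column keeps the
    printed name.
    """
    if which not in ("table1", "table2"):
        raise ValueError("fixture must be 'table1' or 'table2'")
    with resources.files("acetylscope.data").joinpath(f"{which}_fixture.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"symbol": str, "binding_code": str})
    seen: dict[str, int] = {}
    ids = []
    for sym in df["symbol"]:
        seen[sym] = seen.get(sym, 0) + 1
        ids.append(sym if seen[sym] == 1 else f"{sym}.{seen[sym]}")
    df.index = pd.Index(ids, name="gene_id")
    return df


def fixture_concordance(which: str, nc_threshold: float = 1.4):
    """Run the generic concordance classifier over a packaged fixture.

    The fixture's printed codes are translated into classifier inputs:
    '*' rows are excluded from the detected set; 'NC' rows enter the fold
    map with signed fold +1 (below any valid nc_threshold); numeric rows
    carry their printed signed fold. Returns (records, table, totals).
    """
    df = load_table_fixture(which)
    de_like = pd.DataFrame(
        {
            "signed_fc": df["fc"].astype(float),
            "p_value": 0.001,  # all fixture rows were called significant
            "call": np.where(df["fc"].astype(float) > 0, "up", "down"),
        },
        index=df.index,
    )
    detected = set(df.index[df["binding_code"] != "*"])
    folds = {}
    for gid, code in df["binding_code"].items():
        if code == "*":
            continue
        folds[gid] = 1.0 if code == "NC" else float(code)
    records = classify_concordance(de_like, folds, detected, nc_threshold=nc_threshold)
    table, totals = concordance_counts(records)
    return records, table, totals
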