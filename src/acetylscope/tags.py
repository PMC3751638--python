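"""Tag-library quantification: normalization, nearest-TSS assignment,
metagene profiles, enrichment-site calling against input, and gene-set
overlap partitions.

"Nearest promoter" is implemented as nearest TSS: the promoter window is
TSS-centred, so the argmin over promoters and over TSSs coincide.
Equidistant ties break toward the smaller TSS coordinate, then the
lexicographically smaller gene_id.
"""
from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import (
    BindingSite,
    GeneModel,
    TagLibrary,
    TssProfile,
    nearest_tss_index,
    tss_arrays,
)

UNASSIGNED = "__unassigned__"


def normalize_factor(library: TagLibrary) -> float:
    """Tags-per-million scale factor: 1e6 / total tag count."""
    if library.total_count == 0:
        raise ValueError("cannot normalize an empty library")
    return 1e6 / library.total_count


def assign_tags_to_nearest_promoter(
    library: TagLibrary, annotation: Sequence[GeneModel]
) -> dict[str, int]:
    """Raw tag count per gene, each tag going to the gene with the nearest
    TSS on its chromosome.

    Tags on chromosomes absent from the annotation are counted under the
    ``UNASSIGNED`` key; assigned + unassigned always equals total_count.
    """
    if not annotation:
        raise ValueError("annotation must be non-empty")
    index = tss_arrays(annotation)
    counts: dict[str, int] = {g.gene_id: 0 for g in annotation}
    counts[UNASSIGNED] = 0
    for chrom, sub in library.tags.groupby("chrom", sort=False):
        if chrom not in index:
            counts[UNASSIGNED] += len(sub)
            continue
        tss, ids, _ = index[chrom]
        nearest = nearest_tss_index(tss, sub["pos"].to_numpy())
        for i, c in Counter(nearest.tolist()).items():
            counts[ids[i]] += c
    return counts


def normalized_counts(
    library: TagLibrary, annotation: Sequence[GeneModel]
) -> pd.Series:
    """Per-gene tags-per-million (excludes the unassigned bucket)."""
    raw = assign_tags_to_nearest_promoter(library, annotation)
    factor = normalize_factor(library)
    raw.pop(UNASSIGNED, None)
    return pd.Series(raw, name="norm_tags", dtype=float) * factor


def tss_profile(
    library: TagLibrary,
    annotation: Sequence[GeneModel],
    flank: int = 5000,
    binwidth: int = 100,
) -> TssProfile:
    """Metagene profile: histogram of strand-signed tag distances to the
    nearest TSS (upstream negative), density in tags per million.

    Only tags whose signed distance falls in [-flank, flank) contribute.
    """
    if binwidth <= 0:
        raise ValueError("binwidth must be positive")
    if flank <= 0 or flank % binwidth != 0:
        raise ValueError("flank must be a positive multiple of binwidth")
    if not annotation:
        raise ValueError("annotation must be non-empty")
    index = tss_arrays(annotation)
    edges = np.arange(-flank, flank + binwidth, binwidth)
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    for chrom, sub in library.tags.groupby("chrom", sort=False):
        if chrom not in index:
            continue
        tss, _, strands = index[chrom]
        pos = sub["pos"].to_numpy()
        nearest = nearest_tss_index(tss, pos)
        signed = (pos - tss[nearest]) * strands[nearest]
        keep = (signed >= -flank) & (signed < flank)
        counts += np.histogram(signed[keep], bins=edges)[0]
    density = counts * (1e6 / library.total_count) if library.total_count else counts.astype(float)
    return TssProfile(flank=flank, binwidth=binwidth, bin_left=edges[:-1],
                      counts=counts, density=density)


def _window_counts(positions: np.ndarray, starts: np.ndarray, width: int) -> np.ndarray:
    pos = np.sort(positions)
    return np.searchsorted(pos, starts + width, side="left") - np.searchsorted(pos, starts, side="left")


def call_binding_sites(
    ip: TagLibrary,
    input_lib: TagLibrary,
    window: int = 500,
    step: int = 250,
    alpha: float = 1e-5,
    min_fold: float = 2.0,
    pseudocount: float = 0.5,
    bh_correct: bool = False,
) -> list[BindingSite]:
    """Sliding-window Poisson enrichment caller with input correction.

    Per window: expected = input count scaled by the IP/input library-size
    ratio, floored at ``pseudocount``; the window is significant when the
    Poisson upper tail P(X >= ip_count | expected) < alpha and the
    IP/expected ratio >= min_fold. Overlapping or book-ended significant
    windows merge into one site that keeps the minimum p and recomputed
    counts over the merged span. alpha is per-window by default; with
    ``bh_correct`` the Benjamini-Hochberg-adjusted p is thresholded
    instead.
    """
    if input_lib.total_count == 0:
        raise ValueError("input library is empty; cannot form an expectation")
    if ip.total_count == 0:
        raise ValueError("IP library is empty")
    if window < step:
        raise ValueError("window must be >= step")
    scale = ip.total_count / input_lib.total_count

    ip_by_chrom = {c: sub["pos"].to_numpy() for c, sub in ip.tags.groupby("chrom", sort=False)}
    in_by_chrom = {c: sub["pos"].to_numpy() for c, sub in input_lib.tags.groupby("chrom", sort=False)}

    window_rows: list[tuple[str, int, int, float, float]] = []  # chrom, start, ip, expected, p
    all_p: list[np.ndarray] = []
    for chrom in sorted(set(ip_by_chrom) | set(in_by_chrom)):
        ip_pos = ip_by_chrom.get(chrom, np.empty(0, dtype=np.int64))
        in_pos = in_by_chrom.get(chrom, np.empty(0, dtype=np.int64))
        extent = int(max(ip_pos.max(initial=-1), in_pos.max(initial=-1))) + 1
        if extent <= 0:
            continue
        starts = np.arange(0, extent, step)
        ip_c = _window_counts(ip_pos, starts, window)
        in_c = _window_counts(in_pos, starts, window)
        expected = np.maximum(in_c * scale, pseudocount)
        p = stats.poisson.sf(ip_c - 1, expected)
        all_p.append(p)
        for s, ic, ex, pv in zip(starts, ip_c, expected, p):
            window_rows.append((chrom, int(s), int(ic), float(ex), float(pv)))

    if not window_rows:
        return []
    pvec = np.concatenate(all_p)
    if bh_correct:
        order = np.argsort(pvec)
        m = len(pvec)
        adj = np.empty(m)
        ranked = pvec[order] * m / (np.arange(m) + 1)
        adj[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        test_p = adj
    else:
        test_p = pvec

    sig: list[tuple[str, int, int, float]] = []  # chrom, start, end, p
    for (chrom, s, ic, ex, pv), tp in zip(window_rows, test_p):
        if tp < alpha and ic / ex >= min_fold:
            sig.append((chrom, s, s + window, pv))

    sites: list[BindingSite] = []
    for chrom in sorted({c for c, *_ in sig}):
        runs = sorted((s, e, p) for c, s, e, p in sig if c == chrom)
        merged: list[list[float]] = []
        for s, e, p in runs:
            if merged and s <= merged[-1][1]:  # overlap or book-ended
                merged[-1][1] = max(merged[-1][1], e)
                merged[-1][2] = min(merged[-1][2], p)
            else:
                merged.append([s, e, p])
        ip_pos = np.sort(ip_by_chrom.get(chrom, np.empty(0, dtype=np.int64)))
        in_pos = np.sort(in_by_chrom.get(chrom, np.empty(0, dtype=np.int64)))
        for s, e, p in merged:
            s, e = int(s), int(e)
            ip_n = int(np.searchsorted(ip_pos, e) - np.searchsorted(ip_pos, s))
            in_n = int(np.searchsorted(in_pos, e) - np.searchsorted(in_pos, s))
            sites.append(
                BindingSite(chrom=chrom, start=s, end=e, ip_tags=float(ip_n),
                            expected_input_tags=float(max(in_n * scale, pseudocount)),
                            enrichment_p=float(p))
            )
    return sites


def sites_to_genes(
    sites: Iterable[BindingSite],
    annotation: Sequence[GeneModel],
    max_distance: int = 10_000,
) -> tuple[set[str], dict[str, int]]:
    """Annotate each site to the gene whose TSS is nearest its midpoint,
    if within ``max_distance``; return the distinct gene set and per-gene
    site counts."""
    if not annotation:
        raise ValueError("annotation must be non-empty")
    index = tss_arrays(annotation)
    counts: dict[str, int] = {}
    for site in sites:
        if site.chrom not in index:
            continue
        tss, ids, _ = index[site.chrom]
        mid = site.midpoint
        i = int(nearest_tss_index(tss, np.array([mid]))[0])
        if abs(mid - int(tss[i])) <= max_distance:
            counts[ids[i]] = counts.get(ids[i], 0) + 1
    return set(counts), counts


def overlap_partition(
    sets: Mapping[str, set],
    reference: str | None = None,
) -> tuple[dict[str, int], dict[str, float]]:
    """Venn partition of named sets.

    Returns (signature -> count, other-set -> % overlap with the
    reference). Signatures are '&'-joined names in the mapping's key
    order; only non-empty signatures appear; counts sum to |union|.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    names = list(sets)
    union = set().union(*sets.values())
    sig_counts: Counter[str] = Counter()
    for item in union:
        sig = "&".join(n for n in names if item in sets[n])
        sig_counts[sig] += 1
    ref = reference if reference is not None else names[0]
    if ref not in sets:
        raise ValueError(f"reference set {ref!r} not among {names}")
    ref_set = sets[ref]
    pct = {
        n: (100.0 * len(ref_set & sets[n]) / len(ref_set)) if ref_set else 0.0
        for n in names
        if n != ref
    }
    return dict(sig_counts), pct
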