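"""Synthetic annotations, expression matrices, and ChIP tag libraries.

The generator emulates the study design the pipeline was built for: four
treatment groups (chronic saline or drug pretreatment crossed with an
acute saline or drug challenge: SS, SM, MS, MM), an acute transcriptional
response that is mostly up-regulation in drug-naive animals and is blunted
after chronic pretreatment, and IP libraries whose TSS-centred enrichment
intensity couples log-linearly to expression over a uniform background.
Input libraries are pure uniform background. Every operation draws from
its own explicitly seeded numpy Generator; fixed (inputs, seed) gives
byte-identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import GROUPS, ExpressionMatrix, GeneModel, TagLibrary


@dataclass(frozen=True)
class GenomeSpec:
    """Layout of the synthetic genome: chromosomes of equal length packed
    with ``n_genes`` TSSs at least ``min_gene_spacing`` apart."""

    n_chroms: int = 4
    chrom_length: int = 2_500_000
    n_genes: int = 1000
    min_gene_spacing: int = 8000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chroms", "chrom_length", "min_gene_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        if self.n_genes * self.min_gene_spacing > self.n_chroms * self.chrom_length:
            raise ValueError(
                "infeasible packing: n_genes * min_gene_spacing exceeds total genome "
                f"length ({self.n_genes} * {self.min_gene_spacing} > "
                f"{self.n_chroms} * {self.chrom_length})"
            )

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass(frozen=True)
class EffectConfig:
    """Planted differential-expression structure.

    Fractions refer to the two acute contrasts: SM vs SS (drug-naive) and
    MM vs MS (pretreated). Planted SM effects have population fold
    ``effect_fold``; planted MM effects are scaled by ``blunting_factor``
    on the log2 scale, emulating tolerance after chronic exposure.
    """

    n_replicates_per_group: int = 5
    frac_up_SM: float = 0.06
    frac_down_SM: float = 0.026
    frac_up_MM: float = 0.018
    frac_down_MM: float = 0.053
    effect_fold: float = 4.0
    blunting_factor: float = 0.5
    noise_sd_log2: float = 0.25
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 0.6

    def __post_init__(self) -> None:
        if self.n_replicates_per_group < 2:
            raise ValueError("n_replicates_per_group must be >= 2 (variance undefined below)")
        for a, b in ((self.frac_up_SM, self.frac_down_SM), (self.frac_up_MM, self.frac_down_MM)):
            if not (0 <= a <= 1 and 0 <= b <= 1 and a + b <= 1):
                raise ValueError("frac_up + frac_down must lie in [0, 1] per contrast")
        if self.effect_fold <= 1:
            raise ValueError("effect_fold must exceed 1")
        if not 0 <= self.blunting_factor <= 1:
            raise ValueError("blunting_factor must lie in [0, 1]")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be non-negative")


@dataclass(frozen=True)
class TagSimParams:
    """Tag library shape: size, background mixture, TSS spread, coupling.

    ``fragment_length`` defaults inside the sonicated 300-600 bp range;
    tag positions model fragment midpoints (the quantifier applies no
    shift), with an optional 5'-end mode shifting by fragment_length/2.
    """

    library_size: int = 100_000
    background_fraction: float = 0.2
    enrichment_sd: float = 300.0
    expression_coupling_slope: float = 1.0
    fragment_length: int = 450
    five_prime_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.library_size < 1:
            raise ValueError("library_size must be >= 1")
        if not 0 <= self.background_fraction <= 1:
            raise ValueError("background_fraction must lie in [0, 1]")
        if self.enrichment_sd <= 0:
            raise ValueError("enrichment_sd must be positive")
        if self.fragment_length <= 0:
            raise ValueError("fragment_length must be positive")


def simulate_annotation(spec: GenomeSpec) -> list[GeneModel]:
    """Place ``n_genes`` genes with pairwise TSS spacing >= min_gene_spacing.

    Genes are split as evenly as possible across chromosomes; within a
    chromosome, TSS positions are drawn by the slack construction (uniform
    draws over the free length, then spread by the spacing), which yields
    an exact minimum-gap guarantee. Strands are random. Gene lengths are
    uniform in [1000, 10000] bp, truncated at chromosome bounds.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n_genes == 0:
        return []
    per_chrom = np.full(spec.n_chroms, spec.n_genes // spec.n_chroms, dtype=int)
    per_chrom[: spec.n_genes % spec.n_chroms] += 1
    genes: list[GeneModel] = []
    gidx = 0
    s = spec.min_gene_spacing
    for chrom, k in zip(spec.chrom_names(), per_chrom):
        if k == 0:
            continue
        slack = spec.chrom_length - (k - 1) * s - 1
        if slack < 0:
            raise ValueError(
                f"infeasible packing on {chrom}: {k} genes need "
                f"{(k - 1) * s + 1} bp but chromosome is {spec.chrom_length} bp"
            )
        tss = np.sort(rng.integers(0, slack + 1, size=k)) + np.arange(k) * s
        strands = rng.choice(["+", "-"], size=k)
        lengths = rng.integers(1000, 10001, size=k)
        for t, strand, length in zip(tss, strands, lengths):
            t = int(t)
            if strand == "+":
                start, end = t, min(t + int(length), spec.chrom_length)
            else:
                start, end = max(0, t + 1 - int(length)), t + 1
            genes.append(GeneModel(gene_id=f"g{gidx:05d}", chrom=chrom, start=start,
                                   end=end, strand=str(strand)))
            gidx += 1
    return genes


def simulate_expression(
    annotation: Sequence[GeneModel], cfg: EffectConfig, seed: int
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw a four-group expression matrix with planted effects.

    Returns the matrix (linear intensities) and a truth frame indexed by
    gene_id with columns ``SM`` and ``MM`` in {'up', 'down', 'null'}: the
    planted direction for the SM-vs-SS and MM-vs-MS contrasts.
    """
    if not annotation:
        raise ValueError("annotation must be non-empty")
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in annotation]
    n = len(gene_ids)
    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n)

    def plant(frac_up: float, frac_down: float) -> np.ndarray:
        labels = np.full(n, "null", dtype=object)
        n_up = int(round(frac_up * n))
        n_down = int(round(frac_down * n))
        chosen = rng.choice(n, size=n_up + n_down, replace=False)
        labels[chosen[:n_up]] = "up"
        labels[chosen[n_up:]] = "down"
        return labels

    truth = pd.DataFrame(
        {"SM": plant(cfg.frac_up_SM, cfg.frac_down_SM),
         "MM": plant(cfg.frac_up_MM, cfg.frac_down_MM)},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    d = np.log2(cfg.effect_fold)
    shift = {g: np.zeros(n) for g in GROUPS}
    sm_sign = np.where(truth["SM"] == "up", 1.0, np.where(truth["SM"] == "down", -1.0, 0.0))
    mm_sign = np.where(truth["MM"] == "up", 1.0, np.where(truth["MM"] == "down", -1.0, 0.0))
    shift["SM"] = sm_sign * d
    shift["MM"] = mm_sign * d * cfg.blunting_factor  # blunted acute response

    cols: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    for group in GROUPS:
        mu = baseline + shift[group]
        for rep in range(cfg.n_replicates_per_group):
            sample = f"{group}_{rep + 1}"
            noise = rng.normal(0.0, cfg.noise_sd_log2, size=n) if cfg.noise_sd_log2 > 0 else 0.0
            cols[sample] = np.exp2(mu + noise)
            groups[sample] = group
    values = pd.DataFrame(cols, index=truth.index)
    matrix = ExpressionMatrix(values=values, groups=pd.Series(groups, name="group"))
    return matrix, truth


def simulate_tag_library(
    annotation: Sequence[GeneModel],
    condition_mean_expression: Mapping[str, float] | pd.Series,
    params: TagSimParams,
    role: str,
    spec: GenomeSpec,
    sample_id: str = "sim",
    condition: str = "SS",
) -> TagLibrary:
    """Draw one tag library of exactly ``library_size`` single positions.

    role='input' draws every tag from the uniform genome background.
    role='IP' draws ``background_fraction`` of tags from the background and
    the rest at TSS + Normal(0, enrichment_sd) strand-signed offsets, the
    gene picked with probability proportional to
    exp(expression_coupling_slope * log2 expression). Positions are clipped
    to chromosome bounds.
    """
    if role not in ("IP", "input"):
        raise ValueError("role must be 'IP' or 'input'")
    if role == "IP" and not annotation and params.background_fraction < 1:
        raise ValueError("IP simulation needs a non-empty annotation unless background_fraction == 1")
    rng = np.random.default_rng(params.seed)
    chroms = spec.chrom_names()
    L = spec.chrom_length

    n_fg = 0
    if role == "IP":
        n_fg = int(round((1 - params.background_fraction) * params.library_size))
    n_bg = params.library_size - n_fg

    rec_chrom: list[np.ndarray] = []
    rec_pos: list[np.ndarray] = []
    rec_strand: list[np.ndarray] = []

    if n_bg:
        bg_chrom = rng.choice(chroms, size=n_bg)
        bg_pos = rng.integers(0, L, size=n_bg)
        bg_strand = rng.choice(["+", "-"], size=n_bg)
        rec_chrom.append(bg_chrom)
        rec_pos.append(bg_pos)
        rec_strand.append(bg_strand)

    if n_fg:
        expr = pd.Series(condition_mean_expression).reindex([g.gene_id for g in annotation])
        if expr.isna().any():
            missing = expr.index[expr.isna()][:5].tolist()
            raise ValueError(f"expression missing for genes, e.g. {missing}")
        logit = params.expression_coupling_slope * np.log2(expr.to_numpy(dtype=float))
        logit -= logit.max()  # stabilise the softmax
        prob = np.exp(logit)
        prob /= prob.sum()
        gene_idx = rng.choice(len(annotation), size=n_fg, p=prob)
        tss = np.array([g.tss for g in annotation], dtype=np.int64)
        gstrand = np.array([1 if g.strand == "+" else -1 for g in annotation], dtype=np.int64)
        gchrom = np.array([g.chrom for g in annotation], dtype=object)
        offsets = np.rint(rng.normal(0.0, params.enrichment_sd, size=n_fg)).astype(np.int64)
        pos = tss[gene_idx] + gstrand[gene_idx] * offsets
        if params.five_prime_mode:
            # model the sequenced 5' end instead of the fragment midpoint
            read_strand = rng.choice([1, -1], size=n_fg)
            pos = pos - read_strand * (params.fragment_length // 2)
            fg_strand = np.where(read_strand == 1, "+", "-")
        else:
            fg_strand = rng.choice(["+", "-"], size=n_fg)
        pos = np.clip(pos, 0, L - 1)
        rec_chrom.append(gchrom[gene_idx])
        rec_pos.append(pos)
        rec_strand.append(np.asarray(fg_strand))

    tags = pd.DataFrame(
        {
            "chrom": np.concatenate(rec_chrom).astype(str),
            "pos": np.concatenate(rec_pos).astype(np.int64),
            "strand": np.concatenate(rec_strand).astype(str),
        }
    )
    return TagLibrary(sample_id=sample_id, condition=condition, role=role, tags=tags)
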