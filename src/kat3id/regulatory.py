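"""Promoter/enhancer typing, enhancer stitching and super-enhancer calling.

Active promoters are H3K4me3-rich, TSS-proximal regions; enhancers are
H3K4me1-rich regions in introns or intergenic space. Enhancers closer than
5 kb are stitched; stitched domains longer than 5 kb whose nearest gene is
highly expressed (>= 100 RPKM by default) are called super-enhancers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomeAnnotation, Interval, merge_intervals, nearest_tss, overlaps

logger = logging.getLogger(__name__)

ME_PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class RegulatoryElement:
    peak: Interval
    cls: str
    me1_signal: float
    me3_signal: float
    feature: str  # promoter | exon | intron | intergenic
    type: str  # active_promoter | enhancer | other


@dataclass(frozen=True)
class SuperEnhancer:
    span: Interval
    members: tuple[Interval, ...]
    assigned_gene: str
    gene_expression: float  # RPKM of the assigned gene


def type_region(
    peak: Interval,
    me1_signal: float,
    me3_signal: float,
    feature: str,
    cls: str = "",
) -> RegulatoryElement:
    """Type one region as active_promoter, enhancer or other.

    Uses the log ratio of library-normalized H3K4me3 to H3K4me1 signal with a
    pseudo-count of 1: me3-rich at a promoter-feature location is an active
    promoter; me1-rich in an intron or intergenic location is an enhancer.
    """
    if me1_signal < 0 or me3_signal < 0:
        raise ValueError("methylation signals must be non-negative")
    log_ratio = math.log2((me3_signal + ME_PSEUDOCOUNT) / (me1_signal + ME_PSEUDOCOUNT))
    if log_ratio > 0 and feature == "promoter":
        typ = "active_promoter"
    elif log_ratio < 0 and feature in ("intron", "intergenic"):
        typ = "enhancer"
    else:
        typ = "other"
    return RegulatoryElement(peak, cls, me1_signal, me3_signal, feature, typ)


def rpkm(count: float, feature_length_bp: float, library_size: float) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if feature_length_bp <= 0 or library_size <= 0:
        raise ValueError("feature length and library size must be positive")
    return count * 1e9 / (library_size * feature_length_bp)


def expression_rpkm(
    counts: pd.DataFrame,
    annotation: GenomeAnnotation,
    samples: pd.DataFrame | None = None,
    genotype: str = "control",
) -> pd.Series:
    """Mean RPKM per gene across the samples of one genotype.

    Library size is the per-sample total count; feature length is the gene
    body span. KO expression is the phenotype being explained, so the
    super-enhancer gate uses control samples only by default.
    """
    cols = list(counts.columns)
    if samples is not None:
        keep = samples.loc[samples["genotype"] == genotype, "sample"]
        cols = [c for c in cols if c in set(keep)]
        if not cols:
            raise ValueError(f"no samples of genotype {genotype!r}")
    sub = counts[cols]
    lib = sub.sum(axis=0).to_numpy(dtype=float)
    lengths = np.array(
        [annotation.gene(g).span.length if g in annotation else np.nan
         for g in counts.index]
    )
    per_sample = sub.to_numpy(dtype=float) * 1e9 / (lib[None, :] * lengths[:, None])
    return pd.Series(per_sample.mean(axis=1), index=counts.index, name="rpkm")


def stitch_enhancers(
    enhancers: list[Interval], stitch_gap: int = 5000
) -> list[tuple[Interval, tuple[Interval, ...]]]:
    """Stitch enhancers closer than ``stitch_gap``; keep member lists."""
    stitched = merge_intervals(enhancers, max_gap=stitch_gap)
    out = []
    for span in stitched:
        members = tuple(
            e for e in sorted(enhancers) if overlaps(span, e)
        )
        out.append((span, members))
    return out


def call_super_enhancers(
    stitched: list[tuple[Interval, tuple[Interval, ...]]],
    expression: pd.Series,
    annotation: GenomeAnnotation,
    min_length: int = 5000,
    min_expression: float = 100.0,
) -> list[SuperEnhancer]:
    """Keep stitched domains longer than min_length whose nearest gene (by
    TSS distance to the domain midpoint) is expressed at >= min_expression
    RPKM. Domains whose assigned gene has no expression value are skipped
    with a warning."""
    out: list[SuperEnhancer] = []
    for span, members in stitched:
        if span.length <= min_length:
            continue
        hit = nearest_tss(span, annotation)
        if hit is None:
            continue
        gene_id, _ = hit
        if gene_id not in expression.index or pd.isna(expression.loc[gene_id]):
            logger.warning(
                "stitched region %s: no expression for assigned gene %s; skipped",
                span.key(), gene_id,
            )
            continue
        expr = float(expression.loc[gene_id])
        if expr >= min_expression:
            out.append(SuperEnhancer(span, members, gene_id, expr))
    return out


def length_expression_correlation(
    stitched: list[tuple[Interval, tuple[Interval, ...]]],
    expression: pd.Series,
    annotation: GenomeAnnotation,
) -> tuple[float, float, int]:
    """Pearson r and Spearman rho of stitched length vs assigned-gene RPKM."""
    lengths, exprs = [], []
    for span, _ in stitched:
        hit = nearest_tss(span, annotation)
        if hit is None:
            continue
        gene_id, _ = hit
        if gene_id in expression.index and not pd.isna(expression.loc[gene_id]):
            lengths.append(span.length)
            exprs.append(float(expression.loc[gene_id]))
    n = len(lengths)
    if n < 3:
        raise ValueError("need at least 3 stitched regions with expression")
    r = stats.pearsonr(lengths, exprs).statistic
    rho = stats.spearmanr(lengths, exprs).statistic
    return float(r), float(rho), n
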