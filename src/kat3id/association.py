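"""Binding-expression association, gene-set enrichment and overlap report.

Links peak classes to transcriptome change three ways: a distance-decayed
regulatory-potential score per gene with one-sided Kolmogorov-Smirnov tests
of regulated vs unchanged genes (BETA-style), exact hypergeometric
enrichment of marker gene sets among regulated genes, and the reciprocal
overlap between downregulated genes and hypoacetylated regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomeAnnotation, Interval, nearest_tss

RP_WINDOW = 100_000
RP_DECAY_OFFSET = 0.5
RP_DECAY_SLOPE = 4.0


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    universe_size: int  # N
    set_size: int  # K
    regulated_in_universe: int  # n
    overlap: int  # k
    fraction_up: float
    fraction_down: float
    p_hypergeom: float


def regulatory_potential(
    genes: list[str] | GenomeAnnotation,
    peaks: list[Interval],
    annotation: GenomeAnnotation | None = None,
    window: int = RP_WINDOW,
) -> pd.Series:
    """Distance-decayed peak influence per gene.

    Each peak whose midpoint lies within ``window`` of a gene's TSS
    contributes exp(-(0.5 + 4 * d / window)) where d is the midpoint-to-TSS
    distance; contributions add. A peak exactly at the TSS is worth
    e^-0.5 ~= 0.61 and one at the window edge e^-4.5 ~= 0.011.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if isinstance(genes, GenomeAnnotation):
        annotation = genes
        gene_ids = annotation.gene_ids
    else:
        gene_ids = list(genes)
        if annotation is None:
            raise ValueError("annotation required when passing gene ids")
    mids: dict[str, np.ndarray] = {}
    for chrom in annotation.chrom_lengths:
        m = np.array(sorted(p.midpoint for p in peaks if p.chrom == chrom))
        mids[chrom] = m
    scores = {}
    for gid in gene_ids:
        g = annotation.gene(gid)
        m = mids.get(g.chrom, np.array([]))
        if m.size == 0:
            scores[gid] = 0.0
            continue
        d = np.abs(m - g.tss)
        d = d[d <= window]
        scores[gid] = float(
            np.exp(-(RP_DECAY_OFFSET + RP_DECAY_SLOPE * d / window)).sum()
        )
    return pd.Series(scores, name="regulatory_potential")


def beta_association(
    scores: pd.Series,
    de: pd.DataFrame,
    min_class_size: int = 20,
) -> pd.DataFrame:
    """One-sided two-sample KS tests of regulatory potential by DE class.

    Compares the score distribution of downregulated (and upregulated) genes
    against the unchanged ("ns") background. The alternative is that the
    regulated class has stochastically larger scores, so a small p means the
    peak set predicts that direction of regulation. Classes below
    ``min_class_size`` are flagged not-computed (NaN statistics).
    """
    de = de.set_index("feature") if "feature" in de.columns else de
    common = scores.index.intersection(de.index)
    s = scores.loc[common]
    status = de.loc[common, "status"]
    ns = s[status == "ns"].to_numpy()
    rows = []
    for cls in ("down", "up"):
        grp = s[status == cls].to_numpy()
        if len(grp) < min_class_size or len(ns) < min_class_size:
            rows.append(
                {"comparison": f"{cls}_vs_ns", "n_class": len(grp),
                 "n_background": len(ns), "D": np.nan, "p": np.nan,
                 "computed": False}
            )
            continue
        res = stats.ks_2samp(grp, ns, alternative="less")
        rows.append(
            {"comparison": f"{cls}_vs_ns", "n_class": len(grp),
             "n_background": len(ns), "D": float(res.statistic),
             "p": float(res.pvalue), "computed": True}
        )
    return pd.DataFrame(rows)


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact upper tail P[X >= k] for X ~ Hypergeometric(N, K, n)."""
    kmax = min(K, n)
    if k <= max(0, n + K - N):
        return 1.0
    denom = math.comb(N, n)
    total = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, kmax + 1))
    return total / denom


def hypergeom_enrichment(
    gene_set: set[str] | list[str],
    de: pd.DataFrame,
    universe: list[str] | None = None,
    set_name: str = "",
) -> EnrichmentResult:
    """Enrichment of regulated genes in one marker set (exact upper tail).

    N = universe size, K = set size, n = regulated genes in the universe,
    k = regulated members of the set. Also reports the fractions of the set
    up- and downregulated. The universe defaults to all tested genes with
    baseMean > 0.
    """
    de = de.set_index("feature") if "feature" in de.columns else de
    if universe is None:
        universe = list(de.index[de["baseMean"] > 0])
    uni = set(universe)
    gset = set(gene_set)
    if not gset.issubset(uni):
        raise ValueError("gene set is not a subset of the universe")
    regulated = set(de.index[(de["status"] != "ns")]) & uni
    if not regulated.issubset(uni):
        raise ValueError("regulated set is not a subset of the universe")
    N, K, n = len(uni), len(gset), len(regulated)
    k = len(gset & regulated)
    up = set(de.index[de["status"] == "up"])
    down = set(de.index[de["status"] == "down"])
    frac_up = len(gset & up) / K if K else 0.0
    frac_down = len(gset & down) / K if K else 0.0
    return EnrichmentResult(
        set_name=set_name,
        universe_size=N,
        set_size=K,
        regulated_in_universe=n,
        overlap=k,
        fraction_up=frac_up,
        fraction_down=frac_down,
        p_hypergeom=hypergeom_tail(N, K, n, k),
    )


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "set": r.set_name, "N": r.universe_size, "K": r.set_size,
                "n": r.regulated_in_universe, "k": r.overlap,
                "frac_up": r.fraction_up, "frac_down": r.fraction_down,
                "p": r.p_hypergeom,
                "neg_log10_p": -math.log10(r.p_hypergeom) if r.p_hypergeom > 0 else math.inf,
            }
        )
    return pd.DataFrame(rows)


def overlap_report(
    de: pd.DataFrame,
    hypoacetylated_regions: list[Interval],
    annotation: GenomeAnnotation,
) -> dict[str, float | None]:
    """Reciprocal overlap between downregulation and hypoacetylation.

    Each hypoacetylated region is assigned to its nearest-TSS gene. Reports
    (i) the fraction of downregulated genes with at least one assigned
    region, and (ii) the fraction of assigned genes that are downregulated
    (None when no region could be assigned).
    """
    de = de.set_index("feature") if "feature" in de.columns else de
    if len(de) == 0:
        raise ValueError("empty differential-expression table")
    down = set(de.index[de["status"] == "down"])
    assigned: set[str] = set()
    for region in hypoacetylated_regions:
        hit = nearest_tss(region, annotation)
        if hit is not None:
            assigned.add(hit[0])
    frac_down_with_hypo = (
        len(down & assigned) / len(down) if down else 0.0
    )
    frac_hypo_down = len(assigned & down) / len(assigned) if assigned else None
    return {
        "n_down_genes": len(down),
        "n_assigned_genes": len(assigned),
        "frac_down_genes_hypoacetylated": frac_down_with_hypo,
        "frac_hypoacetylated_genes_down": frac_hypo_down,
    }
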