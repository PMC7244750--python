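"""Consensus peak filtering and cell-type classification of co-activator peaks.

The core inference: a conditional knockout removes co-activator binding only
in neurons, so a bulk peak that loses signal in the KO *and* is accessible
in sorted neuronal chromatin is neuronal; a peak that persists and is
accessible is pancellular; a peak that persists but is closed in neurons is
non-neuronal. Lost-but-inaccessible and gained peaks stay ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .intervals import Interval, merge_intervals

PEAK_CLASSES = ("neuronal", "non_neuronal", "pancellular", "ambiguous")


@dataclass(frozen=True)
class PeakClass:
    peak: Interval
    status: str  # diffcall status of the KO-vs-control binding test
    log2fc: float
    padj: float
    atac_accessible: bool
    label: str


def _tree_index(regions: list[Interval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in regions:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def consensus_peaks(
    replicate_peak_sets: list[list[Interval]], min_support: int
) -> list[Interval]:
    """Merged peak regions supported by at least ``min_support`` replicates.

    Peaks from all replicates are merged (gap 0: overlapping or book-ended);
    a merged region is kept iff peaks from >= min_support distinct replicates
    overlap it.
    """
    if not replicate_peak_sets:
        raise ValueError("need at least one replicate peak set")
    if not 1 <= min_support <= len(replicate_peak_sets):
        raise ValueError(
            f"min_support must lie in [1, {len(replicate_peak_sets)}]"
        )
    merged = merge_intervals(
        [iv for peaks in replicate_peak_sets for iv in peaks], max_gap=0
    )
    trees = [_tree_index(peaks) for peaks in replicate_peak_sets]
    kept = []
    for region in merged:
        support = sum(
            1
            for t in trees
            if region.chrom in t and t[region.chrom].overlaps(region.start, region.end)
        )
        if support >= min_support:
            kept.append(region)
    return kept


def _decision(status: str, accessible: bool) -> str:
    if status == "down":
        return "neuronal" if accessible else "ambiguous"
    if status == "ns":
        return "pancellular" if accessible else "non_neuronal"
    return "ambiguous"  # gained peaks: no class reported for these


def classify_kat3_peaks(
    peaks: list[Interval],
    kat3_diff: pd.DataFrame,
    atac_consensus: list[Interval],
) -> list[PeakClass]:
    """Label each co-activator peak neuronal / non-neuronal / pancellular.

    ``kat3_diff`` is a diffcall result table for the KO-vs-control binding
    contrast, indexed by the peak names. Accessibility means >= 1 bp overlap
    with a NeuN+ ATAC consensus peak.
    """
    diff = kat3_diff.set_index("feature") if "feature" in kat3_diff.columns else kat3_diff
    trees = _tree_index(atac_consensus)
    out: list[PeakClass] = []
    for peak in peaks:
        name = peak.name or peak.key()
        if name not in diff.index:
            raise KeyError(f"peak {name} has no differential-binding result")
        row = diff.loc[name]
        accessible = bool(
            peak.chrom in trees and trees[peak.chrom].overlaps(peak.start, peak.end)
        )
        out.append(
            PeakClass(
                peak=peak,
                status=str(row["status"]),
                log2fc=float(row["log2FC"]),
                padj=float(row["padj"]),
                atac_accessible=accessible,
                label=_decision(str(row["status"]), accessible),
            )
        )
    return out


def classification_table(classes: list[PeakClass]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "peak": c.peak.name or c.peak.key(),
                "chrom": c.peak.chrom,
                "start": c.peak.start,
                "end": c.peak.end,
                "status": c.status,
                "log2FC": c.log2fc,
                "padj": c.padj,
                "atac": c.atac_accessible,
                "label": c.label,
            }
            for c in classes
        ],
        columns=["peak", "chrom", "start", "end", "status", "log2FC", "padj",
                 "atac", "label"],
    )
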