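"""End-to-end orchestration: differential calls -> peak classification ->
regulatory typing -> super-enhancers -> association and enrichment reports.

Every stage is a pure function of its inputs, so any stage can be re-run
from its on-disk outputs. ``AnalysisInputs`` can be built directly from a
simulated world (in memory) or from files via :func:`load_inputs`.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import pandas as pd

from . import __version__
from . import association as assoc
from . import diffcall, io as kio, peaks as pk, regulatory as reg
from .config import ConfigError, SimConfig
from .intervals import GenomeAnnotation, Interval, annotate_feature
from .simulate import TruthWorld, simulate_peak_sets, simulate_region_counts, simulate_rna_counts


@dataclass
class AnalysisParams:
    """Thresholds of the analysis; defaults follow the study design."""

    alpha: float = 0.05
    min_abs_lfc: float = 1.0
    strict_lfc: bool = False
    promoter_window: int = 1000
    stitch_gap: int = 5000
    min_se_length: int = 5000
    min_se_rpkm: float = 100.0
    rp_window: int = 100_000
    min_support: int = 2
    min_class_size: int = 20

    def validate(self) -> "AnalysisParams":
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        for name in ("min_abs_lfc", "promoter_window", "stitch_gap",
                     "min_se_length", "min_se_rpkm", "rp_window"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.min_support < 1:
            raise ConfigError("min_support must be >= 1")
        return self


@dataclass
class AnalysisInputs:
    annotation: GenomeAnnotation
    rna_counts: pd.DataFrame
    rna_samples: pd.DataFrame
    region_counts: dict[str, pd.DataFrame]  # assay -> elements x samples
    region_samples: dict[str, pd.DataFrame]
    peaks: list[Interval]  # the peak universe; names match region count rows
    atac_peak_sets: list[list[Interval]]  # replicate-level NeuN+ ATAC calls
    gene_sets: dict[str, list[str]]
    external_de: pd.DataFrame | None = None  # optional DESeq2-style table


@dataclass
class AnalysisResult:
    rna_de: pd.DataFrame
    region_de: dict[str, pd.DataFrame]
    atac_consensus: list[Interval]
    peak_classes: list[pk.PeakClass]
    typed: list[reg.RegulatoryElement]
    stitched: list[tuple[Interval, tuple[Interval, ...]]]
    super_enhancers: list[reg.SuperEnhancer]
    length_expr_corr: tuple[float, float, int] | None
    beta: pd.DataFrame
    enrichment: pd.DataFrame
    overlap: dict
    expression: pd.Series


def inputs_from_world(world: TruthWorld, config: SimConfig) -> AnalysisInputs:
    """Simulate every assay of the study design into an input bundle."""
    rna_counts, rna_samples = simulate_rna_counts(world, config)
    region_counts, region_samples = {}, {}
    for assay in ("KAT3", "H3K27ac", "ATAC", "H3K4me1", "H3K4me3"):
        c, s = simulate_region_counts(world, config, assay)
        region_counts[assay], region_samples[assay] = c, s
    atac_sets = simulate_peak_sets(
        world, config, region_counts["ATAC"], region_samples["ATAC"]
    )
    return AnalysisInputs(
        annotation=world.annotation,
        rna_counts=rna_counts,
        rna_samples=rna_samples,
        region_counts=region_counts,
        region_samples=region_samples,
        peaks=[e.interval for e in world.elements],
        atac_peak_sets=atac_sets,
        gene_sets=world.marker_sets,
    )


def load_inputs(paths: dict[str, str]) -> AnalysisInputs:
    """Build an input bundle from the file map written by write_fixtures."""
    annotation = kio.read_gtf(paths["gtf"])
    region_counts, region_samples = {}, {}
    for assay in ("KAT3", "H3K27ac", "ATAC", "H3K4me1", "H3K4me3"):
        key = assay.lower()
        region_counts[assay] = kio.read_counts(paths[f"{key}_counts"])
        region_samples[assay] = kio.read_sample_sheet(paths[f"{key}_samples"])
    atac_sets = []
    i = 1
    while f"atac_peaks_rep{i}" in paths:
        atac_sets.append(kio.read_bed(paths[f"atac_peaks_rep{i}"]))
        i += 1
    external = None
    if "external_de" in paths:
        external = pd.read_csv(paths["external_de"], sep="\t")
    return AnalysisInputs(
        annotation=annotation,
        rna_counts=kio.read_counts(paths["rna_counts"]),
        rna_samples=kio.read_sample_sheet(paths["rna_samples"]),
        region_counts=region_counts,
        region_samples=region_samples,
        peaks=kio.read_bed(paths["elements_bed"]),
        atac_peak_sets=atac_sets,
        gene_sets=kio.read_gmt(paths["gene_sets"]),
        external_de=external,
    )


def _cpm_means(counts: pd.DataFrame) -> pd.Series:
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    return pd.Series(
        (counts.to_numpy(dtype=float) * 1e6 / lib[None, :]).mean(axis=1),
        index=counts.index,
    )


def run_analysis(inputs: AnalysisInputs, params: AnalysisParams | None = None) -> AnalysisResult:
    """Execute the full analysis on an input bundle."""
    params = (params or AnalysisParams()).validate()
    de_kwargs = dict(alpha=params.alpha, min_abs_lfc=params.min_abs_lfc,
                     strict_lfc=params.strict_lfc)

    if inputs.external_de is not None:
        rna_de = inputs.external_de.copy()
        missing = set(diffcall.DE_COLUMNS) - set(rna_de.columns)
        if missing:
            raise ValueError(f"external DE table lacks columns {sorted(missing)}")
    else:
        rna_de = diffcall.run_diffcall(inputs.rna_counts, inputs.rna_samples, **de_kwargs)

    region_de = {
        assay: diffcall.run_diffcall(
            inputs.region_counts[assay], inputs.region_samples[assay], **de_kwargs
        )
        for assay in ("KAT3", "H3K27ac")
    }

    atac_consensus = pk.consensus_peaks(
        inputs.atac_peak_sets, min_support=min(params.min_support, len(inputs.atac_peak_sets))
    )
    classes = pk.classify_kat3_peaks(inputs.peaks, region_de["KAT3"], atac_consensus)

    me1 = _cpm_means(inputs.region_counts["H3K4me1"])
    me3 = _cpm_means(inputs.region_counts["H3K4me3"])
    typed = []
    for c in classes:
        name = c.peak.name or c.peak.key()
        feature = annotate_feature(c.peak, inputs.annotation, params.promoter_window)
        typed.append(
            reg.type_region(c.peak, float(me1.get(name, 0.0)), float(me3.get(name, 0.0)),
                            feature, cls=c.label)
        )

    neuronal_enh = [t.peak for t in typed if t.type == "enhancer" and t.cls == "neuronal"]
    stitched = reg.stitch_enhancers(neuronal_enh, stitch_gap=params.stitch_gap)
    expression = reg.expression_rpkm(
        inputs.rna_counts, inputs.annotation, inputs.rna_samples, genotype="control"
    )
    ses = reg.call_super_enhancers(
        stitched, expression, inputs.annotation,
        min_length=params.min_se_length, min_expression=params.min_se_rpkm,
    )
    corr = None
    if len(stitched) >= 3:
        corr = reg.length_expression_correlation(stitched, expression, inputs.annotation)

    class_peaks = {
        "all": [c.peak for c in classes],
        "neuronal": [c.peak for c in classes if c.label == "neuronal"],
        "non_neuronal": [c.peak for c in classes if c.label == "non_neuronal"],
        "pancellular": [c.peak for c in classes if c.label == "pancellular"],
    }
    beta_rows = []
    for cls, cls_peaks in class_peaks.items():
        rp = assoc.regulatory_potential(inputs.annotation, cls_peaks, window=params.rp_window)
        tab = assoc.beta_association(rp, rna_de, min_class_size=params.min_class_size)
        tab.insert(0, "class", cls)
        beta_rows.append(tab)
    beta = pd.concat(beta_rows, ignore_index=True)

    universe = [str(g) for g in rna_de.loc[rna_de["baseMean"] > 0, "feature"]]
    uni = set(universe)
    enr = [
        assoc.hypergeom_enrichment(sorted(set(members) & uni), rna_de,
                                   universe=universe, set_name=name)
        for name, members in inputs.gene_sets.items()
    ]
    enrichment = assoc.enrichment_table(enr)

    peak_by_name = {p.name or p.key(): p for p in inputs.peaks}
    hypo = [
        peak_by_name[f]
        for f in region_de["H3K27ac"].loc[region_de["H3K27ac"]["status"] == "down", "feature"]
        if f in peak_by_name
    ]
    overlap = assoc.overlap_report(rna_de, hypo, inputs.annotation)

    return AnalysisResult(
        rna_de=rna_de, region_de=region_de, atac_consensus=atac_consensus,
        peak_classes=classes, typed=typed, stitched=stitched,
        super_enhancers=ses, length_expr_corr=corr, beta=beta,
        enrichment=enrichment, overlap=overlap, expression=expression,
    )


def typed_table(typed: list[reg.RegulatoryElement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "peak": t.peak.name or t.peak.key(), "chrom": t.peak.chrom,
                "start": t.peak.start, "end": t.peak.end, "class": t.cls,
                "me1": t.me1_signal, "me3": t.me3_signal,
                "feature": t.feature, "type": t.type,
            }
            for t in typed
        ],
        columns=["peak", "chrom", "start", "end", "class", "me1", "me3",
                 "feature", "type"],
    )


def superenhancer_table(ses: list[reg.SuperEnhancer]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": s.span.chrom, "start": s.span.start, "end": s.span.end,
                "length": s.span.length, "n_members": len(s.members),
                "gene": s.assigned_gene, "rpkm": s.gene_expression,
            }
            for s in ses
        ],
        columns=["chrom", "start", "end", "length", "n_members", "gene", "rpkm"],
    )


def write_outputs(result: AnalysisResult, out_dir: str,
                  manifest_extra: dict | None = None) -> dict[str, str]:
    """Write every stage table/BED plus a run manifest; returns path map."""
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    def p(name: str, fname: str) -> str:
        paths[name] = os.path.join(out_dir, fname)
        return paths[name]

    result.rna_de.to_csv(p("rna_de", "rna_de.tsv"), sep="\t", index=False)
    for assay, de in result.region_de.items():
        de.to_csv(p(f"{assay.lower()}_de", f"{assay.lower()}_de.tsv"), sep="\t", index=False)
    kio.write_bed(result.atac_consensus, p("atac_consensus", "atac_consensus.bed"))
    cls_tab = pk.classification_table(result.peak_classes)
    cls_tab.to_csv(p("classification", "peak_classification.tsv"), sep="\t", index=False)
    kio.write_bed(
        [Interval(c.peak.chrom, c.peak.start, c.peak.end, name=c.label)
         for c in result.peak_classes],
        p("classified_bed", "peaks_classified.bed"),
    )
    typed_table(result.typed).to_csv(p("typed", "typed_regions.tsv"), sep="\t", index=False)
    kio.write_bed([s for s, _ in result.stitched], p("stitched", "stitched_enhancers.bed"))
    se_tab = superenhancer_table(result.super_enhancers)
    se_tab.to_csv(p("superenhancers", "super_enhancers.tsv"), sep="\t", index=False)
    kio.write_bed(
        [s.span for s in result.super_enhancers], p("se_bed", "super_enhancers.bed")
    )
    result.beta.to_csv(p("beta", "beta_association.tsv"), sep="\t", index=False)
    result.enrichment.to_csv(p("enrichment", "enrichment.tsv"), sep="\t", index=False)
    pd.DataFrame([result.overlap]).to_csv(
        p("overlap", "overlap_report.tsv"), sep="\t", index=False
    )
    manifest = {
        "package": "kat3id",
        "version": __version__,
        "outputs": sorted(os.path.basename(v) for v in paths.values()),
    }
    if result.length_expr_corr is not None:
        r, rho, n = result.length_expr_corr
        manifest["length_expression_correlation"] = {"pearson_r": r, "spearman_rho": rho, "n": n}
    if manifest_extra:
        manifest.update(manifest_extra)
    with open(p("manifest", "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
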