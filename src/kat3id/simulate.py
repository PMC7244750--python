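"""Seeded synthetic study: toy genome, regulatory-element truth and counts.

The generator emulates the data structure of a bulk hippocampal study in
which a co-activator pair is knocked out in neurons only. Bulk ChIP signal
at each regulatory element is a mixture of a neuronal and a non-neuronal
contribution weighted by the neuron fraction of the tissue; the knockout
removes only the neuronal contribution. RNA counts carry a neuronal gene
program that collapses in the knockout while housekeeping genes are
untouched, plus a small upregulated inflammatory-like set.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as kio
from .config import (
    ConfigError,
    ENHANCER_ZONE_GAP_BP,
    GENE_OFFSET_BP,
    SimConfig,
    TERRITORY_BP,
)
from .intervals import GeneModel, GenomeAnnotation, Interval

CLASSES = ("neuronal", "non_neuronal", "pancellular")
ASSAYS = ("KAT3", "H3K27ac", "ATAC", "H3K4me1", "H3K4me3")

# named substreams so every stage draws from an independent, reproducible rng
_STREAMS = {
    "truth": 0,
    "rna": 1,
    "KAT3": 2,
    "H3K27ac": 3,
    "ATAC": 4,
    "H3K4me1": 5,
    "H3K4me3": 6,
    "peaks": 7,
}

# intra-territory element layout (bp)
_PROMOTER_HALF = 400
_CLUSTER_WIDTH = 1800
_CLUSTER_GAP = 1600
_CLUSTER_SIZE = 3
_SINGLETON_WIDTH = 1000
_SINGLETON_STEP = 2500
_MAX_ELEMENTS_PER_GENE = 4  # one promoter + three enhancer slots per zone


def stream_rng(config: SimConfig, name: str) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), _STREAMS[name]])


@dataclass(frozen=True)
class Element:
    """A regulatory element with its ground-truth labels."""

    interval: Interval
    cls: str  # neuronal | non_neuronal | pancellular
    typ: str  # promoter | enhancer
    target_gene: str

    @property
    def accessible(self) -> bool:
        """True if open in neuronal chromatin (neuronal or pancellular)."""
        return self.cls in ("neuronal", "pancellular")


@dataclass
class TruthWorld:
    """Ground truth: annotation, elements, gene programs and marker sets."""

    annotation: GenomeAnnotation
    elements: list[Element]
    gene_programs: dict[str, str]
    marker_sets: dict[str, list[str]]
    se_genes: list[str]
    upregulated_genes: list[str]
    expression_multiplier: dict[str, float]

    def elements_of_class(self, cls: str) -> list[Element]:
        return [e for e in self.elements if e.cls == cls]

    def element_table(self) -> pd.DataFrame:
        rows = [
            {
                "element": e.interval.name,
                "chrom": e.interval.chrom,
                "start": e.interval.start,
                "end": e.interval.end,
                "class": e.cls,
                "type": e.typ,
                "target_gene": e.target_gene,
            }
            for e in self.elements
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "element",
                "chrom",
                "start",
                "end",
                "class",
                "type",
                "target_gene",
            ],
        )

    def genes_of_program(self, program: str) -> list[str]:
        return [g for g, p in self.gene_programs.items() if p == program]


def _make_gene(
    gene_id: str, chrom: str, slot: int, rng: np.random.Generator
) -> GeneModel:
    start = slot * TERRITORY_BP + GENE_OFFSET_BP
    length = int(rng.integers(2000, 8001))
    strand = "+" if rng.random() < 0.5 else "-"
    n_exons = int(rng.integers(2, 5))
    cuts = np.sort(rng.choice(np.arange(200, length - 200), 2 * n_exons - 2, replace=False))
    bounds = [0, *cuts.tolist(), length]
    exons = tuple(
        Interval(chrom, start + bounds[2 * k], start + bounds[2 * k + 1])
        for k in range(n_exons)
        if bounds[2 * k] < bounds[2 * k + 1]
    )
    return GeneModel(gene_id, chrom, strand, start, start + length, exons=exons)


def _enhancer_zone_start(gene: GeneModel) -> int:
    return gene.gene_end + ENHANCER_ZONE_GAP_BP


def _allocate_elements(
    cls: str,
    budget: int,
    genes: list[GeneModel],
    cluster_genes: list[str],
    counter: list[int],
) -> list[Element]:
    """Place ``budget`` elements of one class on their target genes.

    Each gene receives first a promoter at its TSS, then enhancers in its
    intergenic enhancer zone. Genes named in ``cluster_genes`` receive a
    three-enhancer cluster whose stitched span exceeds 5 kb.
    """
    if budget == 0 or not genes:
        return []
    by_id = {g.gene_id: g for g in genes}
    placed: list[Element] = []

    def add(gene: GeneModel, typ: str, start: int, end: int) -> None:
        counter[0] += 1
        name = f"el_{counter[0]:05d}_{cls}"
        placed.append(
            Element(Interval(gene.chrom, start, end, name=name), cls, typ, gene.gene_id)
        )

    # promoters first: one per gene until genes or budget are exhausted
    n_prom = min(budget, len(genes))
    if cls == "neuronal" and n_prom < len(genes):
        raise ConfigError(
            "n_elements_per_class must cover one promoter per neuronal gene"
        )
    for g in genes[:n_prom]:
        add(g, "promoter", max(0, g.tss - _PROMOTER_HALF), g.tss + _PROMOTER_HALF)
    remaining = budget - n_prom
    # clustered enhancers on designated genes
    for gid in cluster_genes:
        if remaining < _CLUSTER_SIZE:
            break
        g = by_id[gid]
        z = _enhancer_zone_start(g)
        for k in range(_CLUSTER_SIZE):
            s = z + k * (_CLUSTER_WIDTH + _CLUSTER_GAP)
            add(g, "enhancer", s, s + _CLUSTER_WIDTH)
        remaining -= _CLUSTER_SIZE
    # singleton enhancers round-robin over the non-cluster genes
    plain = [g for g in genes if g.gene_id not in set(cluster_genes)]
    if not plain:
        plain = genes
    n_slots = _MAX_ELEMENTS_PER_GENE - 1
    slot_of: dict[str, int] = {}
    i = 0
    while remaining > 0:
        g = plain[i % len(plain)]
        k = slot_of.get(g.gene_id, 0)
        if k < n_slots:
            z = _enhancer_zone_start(g)
            s = z + k * _SINGLETON_STEP
            add(g, "enhancer", s, s + _SINGLETON_WIDTH)
            slot_of[g.gene_id] = k + 1
            remaining -= 1
        i += 1
        if i > len(plain) * n_slots + budget:
            raise ConfigError(
                f"cannot place {budget} {cls} elements on {len(genes)} genes"
            )
    return placed


def generate_truth(config: SimConfig) -> TruthWorld:
    """Build the seeded toy genome and ground-truth regulatory landscape."""
    config.validate()
    rng = stream_rng(config, "truth")
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_lengths = {c: config.chrom_length for c in chroms}

    genes: list[GeneModel] = []
    for i in range(config.n_genes):
        chrom = chroms[i % config.n_chromosomes]
        slot = i // config.n_chromosomes
        genes.append(_make_gene(f"gene{i:04d}", chrom, slot, rng))
    annotation = GenomeAnnotation(chrom_lengths, genes)

    order = rng.permutation(config.n_genes)
    n_neu, n_hk = config.n_neuronal_genes, config.n_housekeeping_genes
    neuronal = [genes[i] for i in order[:n_neu]]
    housekeeping = [genes[i] for i in order[n_neu : n_neu + n_hk]]
    other = [genes[i] for i in order[n_neu + n_hk :]]
    programs: dict[str, str] = {}
    for g in neuronal:
        programs[g.gene_id] = "neuronal"
    for g in housekeeping:
        programs[g.gene_id] = "housekeeping"
    for g in other:
        programs[g.gene_id] = "other"

    n_se = min(config.n_se_genes, len(neuronal))
    se_genes = [g.gene_id for g in neuronal[:n_se]]
    n_low = min(config.n_lowexpr_cluster_genes, len(neuronal) - n_se)
    low_genes = [g.gene_id for g in neuronal[n_se : n_se + n_low]]

    mult = {g.gene_id: 1.0 for g in genes}
    for gid in se_genes:
        mult[gid] = config.se_expression_multiplier
    for gid in low_genes:
        mult[gid] = config.low_expression_multiplier

    counter = [0]
    elements = (
        _allocate_elements(
            "neuronal",
            config.n_elements_per_class if neuronal else 0,
            neuronal,
            se_genes + low_genes,
            counter,
        )
        + _allocate_elements(
            "non_neuronal",
            config.n_elements_per_class if other else 0,
            other,
            [],
            counter,
        )
        + _allocate_elements(
            "pancellular",
            config.n_elements_per_class if housekeeping else 0,
            housekeeping,
            [],
            counter,
        )
    )

    n_up = int(round(config.frac_upregulated * len(other)))
    upregulated = [g.gene_id for g in other[:n_up]]

    marker_sets = {
        "neuronal_identity": sorted(g.gene_id for g in neuronal),
        "housekeeping": sorted(g.gene_id for g in housekeeping),
        "non_neuronal_program": sorted(g.gene_id for g in other),
    }
    return TruthWorld(
        annotation=annotation,
        elements=elements,
        gene_programs=programs,
        marker_sets=marker_sets,
        se_genes=se_genes,
        upregulated_genes=upregulated,
        expression_multiplier=mult,
    )


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial with Var = mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def _sample_sheet(prefix: str, genotypes: list[str], n_rep: int) -> pd.DataFrame:
    rows = [
        {"sample": f"{prefix}_{g}_{r + 1}", "genotype": g, "replicate": r + 1}
        for g in genotypes
        for r in range(n_rep)
    ]
    return pd.DataFrame(rows, columns=["sample", "genotype", "replicate"])


def _size_factors(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    lo, hi = config.size_factor_range
    return np.exp(rng.uniform(np.log(lo), np.log(hi), n))


def simulate_rna_counts(
    world: TruthWorld, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-level NB counts for control and KO with the neuronal collapse."""
    rng = stream_rng(config, "rna")
    sheet = _sample_sheet("rna", ["control", "KO"], config.n_replicates)
    gene_ids = world.annotation.gene_ids
    base = np.array(
        [config.baseline_mean * world.expression_multiplier[g] for g in gene_ids]
    )
    ko = base.copy()
    is_neu = np.array(
        [world.gene_programs[g] == "neuronal" for g in gene_ids], dtype=bool
    )
    ko[is_neu] *= 2.0**config.ko_log2fc_neuronal
    is_up = np.isin(np.asarray(gene_ids, dtype=object), world.upregulated_genes)
    ko[is_up] *= 2.0**config.up_log2fc
    sf = _size_factors(rng, len(sheet), config)
    mu = np.where(
        (sheet["genotype"] == "KO").to_numpy()[None, :], ko[:, None], base[:, None]
    ) * sf[None, :]
    counts = _nb_draw(rng, mu, config.dispersion)
    return (
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="feature"),
                     columns=sheet["sample"].tolist()),
        sheet,
    )


def region_mean_control(element: Element, config: SimConfig, assay: str) -> float:
    """Expected bulk control signal at an element for a mixture assay."""
    f = config.neuron_fraction
    mu = config.background_mean
    if element.cls in ("neuronal", "pancellular"):
        mu += f * config.signal_mean_neuronal
    if element.cls in ("non_neuronal", "pancellular"):
        mu += (1.0 - f) * config.signal_mean_nonneuronal
    return mu


def region_mean_ko(element: Element, config: SimConfig, assay: str) -> float:
    """KO removes the neuronal contribution of neuronal-class elements only."""
    if element.cls == "neuronal":
        return config.background_mean
    return region_mean_control(element, config, assay)


def simulate_region_counts(
    world: TruthWorld, config: SimConfig, assay: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-element NB counts for one assay.

    KAT3 and H3K27ac follow the neuron/non-neuron mixture in control and
    lose the neuronal component in KO. ATAC is generated for sorted NeuN+
    nuclei only (control genotype): high at accessible (neuronal and
    pancellular) elements, background elsewhere. H3K4me1/me3 depend on the
    element type (enhancer vs promoter) and carry a single condition.
    """
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}; expected one of {ASSAYS}")
    rng = stream_rng(config, assay)
    ids = [e.interval.name for e in world.elements]
    if assay in ("KAT3", "H3K27ac"):
        sheet = _sample_sheet(assay.lower(), ["control", "KO"], config.n_replicates)
        ctrl = np.array([region_mean_control(e, config, assay) for e in world.elements])
        ko = np.array([region_mean_ko(e, config, assay) for e in world.elements])
        sf = _size_factors(rng, len(sheet), config)
        mu = np.where(
            (sheet["genotype"] == "KO").to_numpy()[None, :], ko[:, None], ctrl[:, None]
        ) * sf[None, :]
    elif assay == "ATAC":
        sheet = _sample_sheet("atac", ["control"], config.n_replicates)
        base = np.array(
            [config.atac_mean if e.accessible else config.background_mean
             for e in world.elements]
        )
        sf = _size_factors(rng, len(sheet), config)
        mu = base[:, None] * sf[None, :]
    else:  # H3K4me1 / H3K4me3
        sheet = _sample_sheet(assay.lower(), ["control"], config.n_replicates)
        enh_high = assay == "H3K4me1"
        base = np.array(
            [
                config.me_high_mean
                if (e.typ == "enhancer") == enh_high
                else config.me_low_mean
                for e in world.elements
            ]
        )
        sf = _size_factors(rng, len(sheet), config)
        mu = base[:, None] * sf[None, :]
    counts = _nb_draw(rng, mu, config.dispersion)
    return (
        pd.DataFrame(counts, index=pd.Index(ids, name="feature"),
                     columns=sheet["sample"].tolist()),
        sheet,
    )


def simulate_peak_sets(
    world: TruthWorld,
    config: SimConfig,
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    genotype: str = "control",
    call_threshold: float = 30.0,
    jitter_bp: int = 50,
    n_noise_peaks: int = 5,
) -> list[list[Interval]]:
    """Replicate-level peak calls derived from simulated counts.

    An element is called in a replicate when its count exceeds
    ``call_threshold``; boundaries get small random jitter and each replicate
    gains a few spurious peaks so that consensus filtering is non-trivial.
    """
    rng = stream_rng(config, "peaks")
    samples = sheet.loc[sheet["genotype"] == genotype, "sample"].tolist()
    chroms = sorted(world.annotation.chrom_lengths)
    sets: list[list[Interval]] = []
    for s in samples:
        called: list[Interval] = []
        for e in world.elements:
            if counts.loc[e.interval.name, s] > call_threshold:
                j1 = int(rng.integers(-jitter_bp, jitter_bp + 1))
                j2 = int(rng.integers(-jitter_bp, jitter_bp + 1))
                start = max(0, e.interval.start + j1)
                end = max(start + 1, e.interval.end + j2)
                called.append(Interval(e.interval.chrom, start, end))
        for _ in range(n_noise_peaks):
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, world.annotation.chrom_lengths[chrom] - 500))
            called.append(Interval(chrom, start, start + 500))
        sets.append(sorted(called))
    return sets


def write_fixtures(world: TruthWorld, config: SimConfig, out_dir: str) -> dict[str, str]:
    """Emit the whole synthetic study as plain-text files.

    Writes a GTF, truth element tables and BEDs, per-assay count matrices
    with sample sheets, replicate-level ATAC/KAT3 peak BEDs and a GMT of
    marker gene sets. Returns a name -> path map. Round-trips losslessly
    through the readers in :mod:`kat3id.io`.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    def p(name: str, fname: str) -> str:
        paths[name] = os.path.join(out_dir, fname)
        return paths[name]

    kio.write_gtf(world.annotation, p("gtf", "annotation.gtf"))
    world.element_table().to_csv(p("elements", "elements.tsv"), sep="\t", index=False)
    kio.write_bed([e.interval for e in world.elements], p("elements_bed", "elements.bed"))
    kio.write_gmt(world.marker_sets, p("gene_sets", "marker_sets.gmt"))

    rna_counts, rna_sheet = simulate_rna_counts(world, config)
    kio.write_counts(rna_counts, p("rna_counts", "rna_counts.tsv"))
    kio.write_sample_sheet(rna_sheet, p("rna_samples", "rna_samples.tsv"))

    for assay in ASSAYS:
        counts, sheet = simulate_region_counts(world, config, assay)
        key = assay.lower()
        kio.write_counts(counts, p(f"{key}_counts", f"{key}_counts.tsv"))
        kio.write_sample_sheet(sheet, p(f"{key}_samples", f"{key}_samples.tsv"))
        if assay in ("ATAC", "KAT3"):
            peak_sets = simulate_peak_sets(world, config, counts, sheet)
            for i, peaks in enumerate(peak_sets, start=1):
                kio.write_bed(peaks, p(f"{key}_peaks_rep{i}", f"{key}_peaks_rep{i}.bed"))
    return paths
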