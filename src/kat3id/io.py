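"""Readers and writers for the on-disk formats the pipeline exchanges.

BED6 (0-based half-open), GTF (1-based inclusive; gene and exon features),
TSV count matrices (first column feature id, header row of sample ids),
sample sheets (sample, genotype, replicate) and GMT gene sets.
"""

from __future__ import annotations


import gffutils
import pandas as pd

from .intervals import GeneModel, GenomeAnnotation, Interval

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_bed(regions: list[Interval], path: str, strand: str = ".") -> None:
    with open(path, "w") as fh:
        for iv in regions:
            name = iv.name or iv.key()
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{iv.score:g}\t{strand}\n"
            )


def read_bed(path: str) -> list[Interval]:
    regions: list[Interval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else ""
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            regions.append(Interval(chrom, start, end, name=name, score=score))
    return regions


def write_gtf(annotation: GenomeAnnotation, path: str) -> None:
    """Write gene and exon features; GTF coordinates are 1-based inclusive."""
    with open(path, "w") as fh:
        for chrom, length in sorted(annotation.chrom_lengths.items()):
            fh.write(f"#!chrom {chrom} length {length}\n")
        for g in sorted(annotation.genes, key=lambda g: (g.chrom, g.gene_start)):
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\tkat3id\tgene\t{g.gene_start + 1}\t{g.gene_end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for k, ex in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tkat3id\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f'{g.strand}\t.\t{attrs} exon_number "{k}";\n'
                )


def read_gtf(path: str) -> GenomeAnnotation:
    """Read gene+exon GTF back into a GenomeAnnotation (0-based in memory).

    Chromosome lengths are taken from ``#!chrom`` header lines when present,
    otherwise from the rightmost feature end per chromosome.
    """
    chrom_lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#!chrom "):
                _, chrom, _, length = line.split()
                chrom_lengths[chrom] = int(length)
            elif not line.startswith("#"):
                break
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons_by_gene: dict[str, list[Interval]] = {}
    for ex in db.features_of_type("exon"):
        gid = ex.attributes["gene_id"][0]
        exons_by_gene.setdefault(gid, []).append(
            Interval(ex.seqid, ex.start - 1, ex.end)
        )
    genes = []
    for g in db.features_of_type("gene"):
        gid = g.attributes["gene_id"][0]
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=g.seqid,
                strand=g.strand,
                gene_start=g.start - 1,
                gene_end=g.end,
                exons=tuple(sorted(exons_by_gene.get(gid, []))),
            )
        )
    if not chrom_lengths:
        for g in genes:
            chrom_lengths[g.chrom] = max(chrom_lengths.get(g.chrom, 0), g.gene_end)
    return GenomeAnnotation(chrom_lengths, genes)


def write_counts(counts: pd.DataFrame, path: str, index_label: str = "feature") -> None:
    counts.to_csv(path, sep="\t", index_label=index_label)


def read_counts(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"duplicate feature or sample ids in {path}")
    return df


def write_sample_sheet(samples: pd.DataFrame, path: str) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "genotype": str})
    required = {"sample", "genotype", "replicate"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample sheet {path} must have columns {sorted(required)}")
    return df


def write_gmt(gene_sets: dict[str, list[str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, "kat3id"] + list(members)) + "\n")


def read_gmt(path: str) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0]:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
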