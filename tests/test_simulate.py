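"""Synthetic-data generator: truth construction, NB counts, fixtures."""

import hashlib
import os

import numpy as np
import pytest

from kat3id import ConfigError, SimConfig, generate_truth
from kat3id.simulate import (
    region_mean_control,
    region_mean_ko,
    simulate_region_counts,
    simulate_rna_counts,
    write_fixtures,
)
from tests.conftest import small_config


def world_signature(world):
    rows = [
        (e.interval.chrom, e.interval.start, e.interval.end, e.cls, e.typ,
         e.target_gene)
        for e in world.elements
    ]
    genes = [
        (g.gene_id, g.chrom, g.strand, g.gene_start, g.gene_end,
         tuple((ex.start, ex.end) for ex in g.exons))
        for g in world.annotation.genes
    ]
    return (tuple(rows), tuple(genes), tuple(sorted(world.gene_programs.items())))


class TestGenerateTruth:
    def test_empty_world(self):
        cfg = SimConfig(n_genes=0, n_elements_per_class=0, seed=1)
        world = generate_truth(cfg)
        assert len(world.annotation) == 0 and world.elements == []

    def test_program_counts_match_config(self):
        cfg = small_config(n_genes=100, frac_neuronal_genes=0.4,
                           frac_housekeeping=0.3, n_elements_per_class=100,
                           chrom_length=3_000_000)
        world = generate_truth(cfg)
        assert len(world.genes_of_program("neuronal")) == 40
        assert len(world.genes_of_program("housekeeping")) == 30
        for cls in ("neuronal", "non_neuronal", "pancellular"):
            assert len(world.elements_of_class(cls)) == 100

    def test_deterministic_for_seed(self):
        cfg = small_config(seed=5)
        assert world_signature(generate_truth(cfg)) == world_signature(generate_truth(cfg))

    def test_different_seed_changes_world(self):
        assert world_signature(generate_truth(small_config(seed=5))) != world_signature(
            generate_truth(small_config(seed=6))
        )

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(frac_neuronal_genes=1.2).validate()
        with pytest.raises(ConfigError):
            SimConfig(n_replicates=1).validate()
        with pytest.raises(ConfigError):
            SimConfig(baseline_mean=-1).validate()
        with pytest.raises(ConfigError):
            # budget cannot cover one promoter per neuronal gene
            generate_truth(small_config(n_elements_per_class=5))

    def test_world_invariants(self, world):
        gene_ids = set(world.annotation.gene_ids)
        for e in world.elements:
            assert e.target_gene in gene_ids
            if e.typ == "promoter":
                tss = world.annotation.gene(e.target_gene).tss
                assert abs(e.interval.midpoint - tss) <= 1000
        # every neuronal gene carries at least one neuronal element
        covered = {e.target_gene for e in world.elements_of_class("neuronal")}
        assert set(world.genes_of_program("neuronal")) <= covered
        # housekeeping genes carry pancellular promoter elements
        hk_prom = {
            e.target_gene
            for e in world.elements_of_class("pancellular")
            if e.typ == "promoter"
        }
        assert set(world.genes_of_program("housekeeping")) <= hk_prom

    def test_gene_bodies_non_overlapping(self, world):
        by_chrom = {}
        for g in world.annotation.genes:
            by_chrom.setdefault(g.chrom, []).append((g.gene_start, g.gene_end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert s2 - e1 >= 10_000


class TestRnaCounts:
    def test_null_effect_recovers_baseline(self):
        """With no dispersion, no effect and unit size factors, every
        per-gene mean lands within 3 SE of the configured baseline."""
        cfg = small_config(dispersion=0.0, ko_log2fc_neuronal=0.0,
                           frac_upregulated=0.0, n_replicates=10,
                           size_factor_range=(1.0, 1.0),
                           se_expression_multiplier=1.0,
                           low_expression_multiplier=1.0)
        world = generate_truth(cfg)
        counts, _ = simulate_rna_counts(world, cfg)
        means = counts.mean(axis=1)
        se = np.sqrt(cfg.baseline_mean / counts.shape[1])
        # 3 SE covers ~99.7% per gene; allow a single outlier across 60 genes
        assert (np.abs(means - cfg.baseline_mean) < 3 * se + 1e-9).mean() >= 0.98

    def test_ko_fold_change_matches_formula(self):
        cfg = small_config(ko_log2fc_neuronal=-2.0, baseline_mean=200.0,
                           n_replicates=10, size_factor_range=(1.0, 1.0),
                           se_expression_multiplier=1.0,
                           low_expression_multiplier=1.0)
        world = generate_truth(cfg)
        counts, sheet = simulate_rna_counts(world, cfg)
        neu = world.genes_of_program("neuronal")
        ko_cols = sheet.loc[sheet["genotype"] == "KO", "sample"]
        ct_cols = sheet.loc[sheet["genotype"] == "control", "sample"]
        ratio = counts.loc[neu, ko_cols].to_numpy().mean() / counts.loc[
            neu, ct_cols
        ].to_numpy().mean()
        n = len(neu) * len(ko_cols)
        se = np.sqrt((200 * 0.25 + cfg.dispersion * (200 * 0.25) ** 2) / n) / 200
        assert abs(ratio - 0.25) < 3 * se

    def test_housekeeping_unchanged(self, world, default_config):
        counts, sheet = simulate_rna_counts(world, default_config)
        hk = world.genes_of_program("housekeeping")
        ko = counts.loc[hk, sheet.loc[sheet["genotype"] == "KO", "sample"]]
        ct = counts.loc[hk, sheet.loc[sheet["genotype"] == "control", "sample"]]
        assert abs(np.log2(ko.to_numpy().mean() / ct.to_numpy().mean())) < 0.25

    def test_program_asymmetry_by_construction(self, world):
        n_down = len(world.genes_of_program("neuronal"))
        assert n_down > len(world.upregulated_genes)


class TestRegionCounts:
    def test_unknown_assay(self, world, default_config):
        with pytest.raises(ValueError, match="assay"):
            simulate_region_counts(world, default_config, "CTCF")

    def test_ko_spares_non_neuronal(self, world, default_config):
        for e in world.elements_of_class("non_neuronal"):
            assert region_mean_ko(e, default_config, "KAT3") == region_mean_control(
                e, default_config, "KAT3"
            )

    def test_mixture_formula(self, world):
        cfg = small_config(neuron_fraction=0.8)
        w = generate_truth(cfg)
        e_neu = w.elements_of_class("neuronal")[0]
        e_pan = w.elements_of_class("pancellular")[0]
        f, bg = 0.8, cfg.background_mean
        assert region_mean_control(e_neu, cfg, "KAT3") == pytest.approx(
            bg + f * cfg.signal_mean_neuronal
        )
        assert region_mean_ko(e_neu, cfg, "KAT3") == pytest.approx(bg)
        assert region_mean_control(e_pan, cfg, "KAT3") == pytest.approx(
            bg + f * cfg.signal_mean_neuronal + (1 - f) * cfg.signal_mean_nonneuronal
        )

    def test_monte_carlo_mean_converges_to_mixture(self):
        """Sample mean over ~1000 replicates tracks the mixture formula to
        within 5% relative error at every element."""
        cfg = small_config(n_replicates=1000, size_factor_range=(1.0, 1.0))
        w = generate_truth(cfg)
        counts, sheet = simulate_region_counts(w, cfg, "KAT3")
        ctrl = counts[sheet.loc[sheet["genotype"] == "control", "sample"]]
        expected = np.array([region_mean_control(e, cfg, "KAT3") for e in w.elements])
        rel = np.abs(ctrl.mean(axis=1).to_numpy() - expected) / expected
        assert rel.max() < 0.05

    def test_atac_restricted_to_accessible(self, world, default_config):
        counts, sheet = simulate_region_counts(world, default_config, "ATAC")
        assert set(sheet["genotype"]) == {"control"}
        means = counts.mean(axis=1)
        for e in world.elements:
            m = means[e.interval.name]
            if e.accessible:
                assert m > 5 * default_config.background_mean
            else:
                assert m < 5 * default_config.background_mean


class TestFixtures:
    def checksums(self, paths):
        out = {}
        for name, p in sorted(paths.items()):
            with open(p, "rb") as fh:
                out[name] = hashlib.sha256(fh.read()).hexdigest()
        return out

    def test_fixture_checksums_deterministic(self, tmp_path):
        cfg = small_config(seed=21)
        w = generate_truth(cfg)
        p1 = write_fixtures(w, cfg, str(tmp_path / "a"))
        p2 = write_fixtures(generate_truth(cfg), cfg, str(tmp_path / "b"))
        assert self.checksums(p1) == self.checksums(p2)

    def test_empty_world_writes_valid_files(self, tmp_path):
        cfg = SimConfig(n_genes=0, n_elements_per_class=0, seed=1)
        w = generate_truth(cfg)
        paths = write_fixtures(w, cfg, str(tmp_path))
        for p in paths.values():
            assert os.path.exists(p)
        with open(paths["rna_counts"]) as fh:
            header = fh.readline().strip().split("\t")
        assert header[0] == "feature"
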