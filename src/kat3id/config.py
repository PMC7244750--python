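"""Simulation and pipeline configuration objects."""

from __future__ import annotations

from dataclasses import asdict, dataclass


class ConfigError(ValueError):
    """Raised when a configuration violates its documented invariants."""


# Territory layout constants used by the synthetic genome: each gene owns a
# fixed-width slot so that enhancers stay closest to their own TSS and
# clusters from neighbouring genes can never stitch together (gap >= 5 kb).
TERRITORY_BP = 50_000
GENE_OFFSET_BP = 1_000
ENHANCER_ZONE_GAP_BP = 6_000
ENHANCER_ZONE_BP = 10_000


@dataclass
class SimConfig:
    """Parameters of the synthetic hippocampal study.

    Counts are negative binomial with Var = mu + dispersion * mu^2. The bulk
    tissue is a mixture of a neuron fraction ``neuron_fraction`` and
    non-neuronal cells; the knockout removes co-activator signal only from
    the neuronal compartment.
    """

    n_chromosomes: int = 2
    chrom_length: int = 6_000_000
    n_genes: int = 240
    frac_neuronal_genes: float = 0.35
    frac_housekeeping: float = 0.35
    n_elements_per_class: int = 220
    neuron_fraction: float = 0.4
    baseline_mean: float = 200.0
    dispersion: float = 0.05
    ko_log2fc_neuronal: float = -2.5
    n_replicates: int = 3
    seed: int = 0
    # secondary knobs (defaults are the study conditions; see docs/methods.md)
    background_mean: float = 5.0
    signal_mean_neuronal: float = 300.0
    signal_mean_nonneuronal: float = 300.0
    atac_mean: float = 150.0
    me_high_mean: float = 200.0
    me_low_mean: float = 10.0
    frac_upregulated: float = 0.05
    up_log2fc: float = 1.5
    n_se_genes: int = 15
    n_lowexpr_cluster_genes: int = 10
    se_expression_multiplier: float = 8.0
    low_expression_multiplier: float = 0.05
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    allow_overlapping_genes: bool = False

    def validate(self) -> "SimConfig":
        c = self
        if c.n_chromosomes < 1 or c.chrom_length < 1:
            raise ConfigError("need at least one chromosome of positive length")
        if c.n_genes < 0 or c.n_elements_per_class < 0 or c.n_replicates < 2:
            raise ConfigError("n_genes/n_elements >= 0 and n_replicates >= 2 required")
        for name in ("frac_neuronal_genes", "frac_housekeeping", "frac_upregulated"):
            v = getattr(c, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if c.frac_neuronal_genes + c.frac_housekeeping > 1.0:
            raise ConfigError("gene program fractions exceed 1")
        if not 0.0 <= c.neuron_fraction <= 1.0:
            raise ConfigError("neuron_fraction must lie in [0, 1]")
        if c.baseline_mean <= 0 or c.dispersion < 0 or c.background_mean <= 0:
            raise ConfigError("means must be positive and dispersion non-negative")
        lo, hi = c.size_factor_range
        if not (0 < lo <= hi):
            raise ConfigError("size_factor_range must satisfy 0 < lo <= hi")
        genes_per_chrom = -(-c.n_genes // c.n_chromosomes) if c.n_genes else 0
        if genes_per_chrom * TERRITORY_BP > c.chrom_length:
            raise ConfigError(
                "chrom_length too small for the gene territories: need "
                f"{genes_per_chrom * TERRITORY_BP} bp per chromosome"
            )
        return c

    def to_dict(self) -> dict:
        d = asdict(self)
        d["size_factor_range"] = list(self.size_factor_range)
        return d

    @property
    def n_neuronal_genes(self) -> int:
        return int(round(self.n_genes * self.frac_neuronal_genes))

    @property
    def n_housekeeping_genes(self) -> int:
        return int(round(self.n_genes * self.frac_housekeeping))
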