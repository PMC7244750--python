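# Methods

## Model and rationale

The package operationalizes a cell-type deconvolution argument. Bulk ChIP
signal of a ubiquitously expressed co-activator at a regulatory element is
modeled as a mixture over the cell populations of the tissue:

```
μ_control(element) = μ_bg + f·μ_neu·1[class ∈ {neuronal, pancellular}]
                          + (1−f)·μ_non·1[class ∈ {non_neuronal, pancellular}]
```

where `f` is the neuron fraction of the bulk tissue. A neuron-restricted
knockout removes only the neuronal contribution; an element whose entire
signal was neuronal therefore drops to background, while pancellular and
non-neuronal elements are unchanged. The classifier turns this into a
decision table on two observables: the KO-vs-control differential-binding
status of the element (negative-binomial Wald test on region counts) and
whether the element overlaps (≥ 1 bp) a consensus accessibility peak from
sorted neuronal nuclei. Gained peaks and lost-but-inaccessible peaks are
reported as `ambiguous` rather than forced into a class — the three-class
scheme has no natural slot for them, and silently mislabeling them would
bias downstream association tests.

Note the KO leaves the neuronal mixture component of *pancellular* elements
in place. This encodes the empirical observation the classifier relies on —
shared sites retain strong signal after the neuron-restricted KO — without
modeling why (redundant acetyltransferases, non-neuronal dominance, or
compensation); the simulator reproduces the observable, not its mechanism.

## Differential testing

`diffcall` is a deliberately small two-group NB caller applied uniformly to
gene and region counts:

- **Normalization**: median-of-ratios size factors over features positive in
  all samples, rescaled to geometric mean 1; an add-1 pseudo-reference
  fallback is available for sparse matrices.
- **Effect size**: `log2FC = log2((mean_KO + 0.5) / (mean_ctrl + 0.5))`. The
  0.5 pseudo-count stabilizes fold changes at low counts.
- **Variance**: per-feature pooled method-of-moments dispersion under
  `Var = μ + αμ²`, floored at 1e−8. Because a count `X_j ~ NB(s_j q, α)`
  normalized by its size factor has variance `q/s_j + αq²`, the Poisson term
  carries a `mean(1/s_j)` factor per group; omitting it measurably
  miscalibrates the test when library sizes differ.
- **Reference distribution**: the Wald statistic (delta-method SE on the
  log2 scale) is referred to a Student t with `n1 + n2 − 2` degrees of
  freedom. With a plug-in variance at n = 5 per group, a normal reference
  rejects ~8.5% of null features at the 5% level; the t reference is the
  standard small-sample correction and brings the type-I error to ~5%
  (verified by simulation in the test suite).
- **Multiple testing**: Benjamini–Hochberg step-up (statsmodels), followed
  by the study thresholds FDR < 0.05 and |log2FC| ≥ 1. The boundary value
  counts as significant; a strict comparator is available
  (`strict_lfc=True`) because written conventions differ on this point.

Known limitations: no dispersion shrinkage, no outlier (Cook's) filtering,
no independent filtering, two-group designs only. A realized-FDR caveat: the
fold-change gate is part of the error control in practice — under strong
composition bias (a quarter of features with large planted effects),
BH-adjusted p-values alone give a realized FDR of ~18% because
median-of-ratios normalization absorbs part of the signal into the size
factors and shifts the nulls, while the combined padj + |log2FC| ≥ 1 call
keeps it below 1%.

Exact scale invariance of p-values under multiplying one sample's counts by
a constant is not attainable: scaling counts genuinely changes that
sample's relative counting noise. Normalized means (hence log2FC) are
invariant up to the pseudo-count; p-values agree to ~0.05 and the
thresholded calls exactly.

## Interval conventions

All in-memory coordinates are 0-based half-open; GTF is converted on
read/write. Merging/stitching chains intervals whose gap is *strictly*
smaller than the stitch distance ("closer than 5 kb": a gap of exactly
5 kb stays separate). Peak-to-feature assignment (promoter / exon / intron /
intergenic) evaluates the peak midpoint with precedence
promoter > exon > intron; midpoint rather than any-overlap was chosen
because peaks are narrow relative to genes, and the promoter window is
± 1 kb of a TSS. Closest-gene assignment minimizes |midpoint − TSS| with
ties broken by lexicographic gene id, making results independent of
annotation order. One TSS per gene; isoform resolution is out of scope.

## Regulatory typing and super-enhancers

A classified peak is an **active promoter** if
`log2((me3 + 1)/(me1 + 1)) > 0` on library-normalized (CPM) signal *and*
its feature label is promoter; an **enhancer** if the ratio is negative
*and* it lies in an intron or intergenic space; otherwise **other**. The
pseudo-count of 1 on CPM-scale signal keeps the ratio defined at empty
regions; the source data gives only "rich/enriched", so the sign of the
log-ratio is the natural parameter-free cutoff.

Neuronal enhancers are stitched at 5 kb. A stitched domain is a
**super-enhancer** when its span exceeds 5 kb and its assigned gene —
nearest TSS to the domain midpoint, the ROSE-style single-gene assignment —
is expressed at ≥ 100 RPKM. Expression for this gate is the mean RPKM over
*control* samples only, since KO expression is the phenotype being
explained. RPKM uses the gene-body span as feature length and the
per-sample total count as library size. The classical signal-ranking
("hockey-stick") cutoff is intentionally not implemented; the
length-plus-expression criterion is the analysis content here.

## Association statistics

- **Regulatory potential**: `Σ exp(−(0.5 + 4Δ))`, `Δ = d/window`, over peaks
  with midpoint-to-TSS distance `d ≤ window` (default 100 kb). The decay
  constants follow the published binding-and-expression target analysis
  method; window and decay are exposed as parameters.
- **KS association**: one-sided two-sample KS of the RP distribution of
  down- (or up-) regulated genes against the unchanged background, with the
  alternative "regulated genes have larger potential". Classes under 20
  genes are flagged not-computed rather than tested.
- **Enrichment**: exact hypergeometric upper tail `P[X ≥ k]` by integer
  combinatorics (`math.comb`), with the universe defaulting to all tested
  genes with positive base mean.
- **Overlap report**: hypoacetylated regions (H3K27ac status down) are
  assigned to their nearest-TSS gene; the report gives the fraction of
  downregulated genes with ≥ 1 assigned region and the reciprocal fraction
  of assigned genes that are downregulated (NA when nothing is assigned).

## The synthetic study

`generate_truth` builds a genome of fixed 50-kb gene territories (gene body
at a 1-kb offset, an enhancer zone 6–16 kb downstream of the gene end).
The layout guarantees that every element is closest to its own gene's TSS
and that enhancer clusters of neighbouring genes can never stitch together,
so closest-gene assignment is unambiguous by construction; gene bodies are
non-overlapping with ≥ 10 kb spacing. Default study conditions: 240 genes
on 2 chromosomes, 35% neuronal / 35% housekeeping gene programs,
220 elements per class (one promoter per program gene plus enhancers),
3 replicates per genotype, baseline mean 200, dispersion α = 0.05,
KO effect on neuronal genes −2.5 log2 units, and a 5% upregulated
inflammatory-like set at +1.5 — producing the characteristic preponderance
of downregulation. Per-sample size factors are drawn log-uniform in
[0.7, 1.4] so normalization is exercised non-trivially; background counts
are NB with mean 5 rather than zero so thresholds face real noise.

The neuron fraction of bulk hippocampal tissue is not a published constant;
the default `f = 0.4` is a realistic mid-range value for neuron-rich
forebrain tissue and is a free parameter (`neuron_fraction`). At `f = 0`
the generator produces a tissue without neurons, which the test suite uses
as a negative control: no peaks may classify as neuronal beyond FDR-level
noise.

Fifteen neuronal genes carry three-enhancer clusters (stitched span
8.6 kb) and an 8× expression multiplier — the planted super-enhancers. Ten
further neuronal genes carry equally long clusters but 0.05× expression,
and the remaining neuronal genes carry short singleton enhancers with
baseline expression: the SE caller must therefore use *both* the length and
the expression gate to reach precision/recall ≥ 0.9, and the length–
expression correlation is positive by construction but far from 1.

Replicate-level peak calls for consensus filtering are derived by
thresholding simulated counts (call threshold 30 against background mean
5), with ±50 bp boundary jitter and five spurious peaks per replicate, so
the ≥ 2-replicate support filter does real work. This support filter
replaces IDR, which needs per-peak score distributions the count model does
not produce.

What the generator does **not** emulate: fragment-level coverage and peak
shape, single-nucleus data, isoform structure, chromatin contact geometry,
correlated dispersion across genes, batch effects, and any genome sequence.
Passing tests therefore demonstrate the correctness and calibration of the
analysis logic under the stated statistical model, not performance on real
sequencing data.

## Determinism and numerics

All randomness flows from one seed through named substreams
(`numpy.random.default_rng([seed, stream])`) per simulation stage, so a
fixture directory and every pipeline output are byte-identical across runs
with the same configuration. Degenerate inputs have defined behaviour:
all-zero features test at p = 1 / log2FC = 0; an empty world writes valid
headers; stitched domains without an expression value are skipped with a
logged warning; a chromosome without genes yields a none-marker from
closest-gene assignment.

Problem sizes used by the test suite and the acceptance script (240 genes,
660 elements, 2000-feature calibration runs, 200-replicate permutation
nulls, 3 seeds for truth recovery) were chosen as the smallest scales at
which the planted effects and the calibration bands are stable across
seeds; the whole suite runs in well under a minute.
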