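# chipquant

Quantitative ChIP-seq normalization across highly variant experimental
conditions, with gene-level integration of transcriptomics — built for
experiments (hypoxia time courses, drug treatments, differentiation) in
which *most* of the epigenome changes, so the usual read-count scaling
assumption ("few differences between conditions") breaks down.

The package compares H3K4me3 (activation-associated) and H3K27me3
(repression-associated) peak tracks across four conditions of an
oxygenation time course — normoxia (t0), 8 h hypoxia (t8), 24 h hypoxia
(t24) and 8 h reoxygenation (t+8) — but the machinery is generic to any
four-state design.

## The method

ChIP-seq signal between samples differs by an unknown per-sample scale
(IP efficiency, depth). Without spike-in controls, the scale can be fixed
against *invariant references* found in the data itself:

**Invariant regions (H3K27me3).** Regions of sustained, saturated
repressive marking — enrichment present across the whole cell population
that cannot increase further — are found with a peak-centred sliding-window
scan. Peak heights are dichotomized at the per-sample 90th percentile; each
20-kb window centred on a peak is tested for an excess of positive peaks
with a one-sided χ² goodness-of-fit test

&nbsp;&nbsp;&nbsp;&nbsp;X² = (O₊ − nπ)²/nπ + (O₋ − n(1−π))²/n(1−π),&nbsp;&nbsp;
p = P(χ²₁ ≥ X²) if O₊ > nπ else 1,

where π is the sample's global positive fraction. Windows with p < 10⁻⁵ are
merged, and only regions significant in **all four** conditions are kept.
The cumulative peak AUC over these regions yields per-sample scaling
factors, sᵢ = AUCᵢ / min₍ⱼ₎ AUCⱼ ≥ 1, by which every peak height and AUC is
divided.

**Invariant genes (H3K4me3).** Genes with invariant transcription should
carry invariant promoter H3K4me3. Genes with expression CV < 0.10 across
all arrays and expression above background anchor the H3K4me3 scale: the
peak AUC inside the strand-aware TSS window (−1000..+100 bp) is summed over
those genes, and scaling factors are derived the same way.

**Background threshold.** After normalization, a single log2 peak-height
cutoff is calibrated as the smallest cutoff at which per-gene H3K27me3 AUC
correlates (Spearman, near-maximal significant ρ) with an independent
reference ChIP of an H3K27me3 reader protein; biological significance is
set at twice that background (+1 log2). The threshold is validated against
consistently highly expressed genes (above the per-array 95th percentile on
every array), whose repressive-mark peaks must sit below background.

**Gene-level integration.** A gene region is 5′ TSS → 3′ end ± 5 kb; a gene
is *marked* when at least one supra-background peak lies inside, *bivalent*
when marked by both modifications. The package reports per-condition mean
log2 gene AUC with fold changes FC = 2^(Δ mean log2 AUC) and Wilcoxon
signed-rank p values, CpG promoter classes (HCP/ICP/LCP by
observed/expected CpG ratio and GC fraction in 500-bp windows over
−700..+200), marked/bivalent counts per class, and overlaps with reference
gene sets (hypergeometric test).

Because the original study's raw data were never deposited, the package
ships a first-class synthetic-data generator (`chipquant.synthetic`) that
plants all of this structure — scale distortions, saturated regions, a
noise floor, responsive genes, bivalent CpG-rich promoters — as recoverable
ground truth.

## Worked example

```python
from chipquant import CONDITIONS, Condition, Mark
from chipquant.synthetic import SyntheticConfig, generate_dataset
from chipquant.sustained import normalize_by_sustained_regions
from chipquant.invariant import normalize_by_invariant_genes
from chipquant.thresholds import build_threshold_report
from chipquant.integrate import call_marked, call_bivalent

ds = generate_dataset(SyntheticConfig(), seed=1)   # planted factors 1/1.5/2/1.2

k27 = normalize_by_sustained_regions(
    {c: ds.peaksets[(Mark.H3K27ME3, c)] for c in CONDITIONS})
k4, invariant = normalize_by_invariant_genes(
    {c: ds.peaksets[(Mark.H3K4ME3, c)] for c in CONDITIONS},
    ds.expression, ds.genes)
print("H3K27me3 factors:", {c.value: round(f, 3) for c, f in k27.scaling_factors.items()})
print("H3K4me3 factors: ", {c.value: round(f, 3) for c, f in k4.scaling_factors.items()})

report = build_threshold_report(
    k27.normalized, ds.peaksets[(Mark.REFERENCE, Condition.T0)],
    ds.genes, ds.expression)
print("background log2: ", report.background_log2,
      " biological log2:", report.biological_log2)

e4 = call_marked(k4.normalized[Condition.T0], ds.genes, report.background_log2)
e27 = call_marked(k27.normalized[Condition.T0], ds.genes, report.background_log2)
print("bivalent at t0:  ", sum(c.state == "bivalent"
                               for c in call_bivalent(e4, e27).values()))
```

prints

```
H3K27me3 factors: {'t0': 1.0, 't8': 1.499, 't24': 2.002, 't_plus8': 1.199}
H3K4me3 factors:  {'t0': 1.0, 't8': 1.507, 't24': 2.024, 't_plus8': 1.203}
background log2:  3.0  biological log2: 4.0
bivalent at t0:   240
```

The recovered factors undo the planted per-sample distortions
{1.0, 1.5, 2.0, 1.2} to within ~1 %, the calibrated background (3.0) sits
one grid step above the planted noise floor (2.9 log2), the biological
threshold is exactly two-fold higher, and the 240 bivalent calls at t0
coincide exactly with the genes planted as bivalent.

The same stages are available as a CLI: `chipquant simulate`,
`normalize-k27`, `normalize-k4`, `threshold`, `integrate` (see
`chipquant --help`); each stage writes TSV/BED/WIG artifacts plus a run
manifest with input digests, so identical seeds give byte-identical runs.

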