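# Methods

## Scope and shape

`chromcycle` implements the *downstream* half of a two-generation histone
PTM ChIP-seq study: it starts from binned coverage (bedGraph), a genome
annotation (GFF3), transposon intervals (BED) and expression tables (TSV),
and ends at feature partitions, peak/TSS associations, broad-domain
statistics, chromatin-state transitions and gene-pair promoter analyses.
Read mapping, fragment modelling and read-level peak calling are out of
scope; the built-in Poisson bin caller is a transparent stand-in for a
production caller, not a re-implementation of one.

All internal coordinates are 0-based half-open; GFF3 (1-based closed) and
BED/bedGraph are converted at the boundary. TSS and TES are strand-aware
points on the boundary lattice (a minus-strand gene spanning [100, 200) has
TSS = 200). Every stochastic step flows from one `numpy` `SeedSequence`, so
a (config, seed) pair reproduces a dataset byte for byte.

## The analysis pipeline

**Feature partition.** Each bp belongs to exactly one of: upstream-TSS
window (500 bp 5' of the TSS, truncated at the scaffold edge or a
neighbouring gene body), first exon, other exon, first intron, other
intron, intergenic. Collisions between overlapping genes resolve by that
priority order — the TSS window is the analysis focus and must not be
swallowed by a neighbour's intron. Intergenic and intron classes are
subdivided by transposon overlap (transposons are input intervals; the
generator emits the ≥ 400 bp convention).

**Peak caller.** Counts are compared per bin to
λ = max(global control mean, 10 kb local control mean), library-scaled;
p-values are Poisson upper tails, BH-corrected genome-wide, thresholded at
FDR 0.01 (the published pipeline's threshold). Significant bins merge
across gaps of ≤ 1 bin (narrow) or ≤ 1 kb (broad); peaks shorter than two
bins are dropped, which suppresses isolated false-positive bins. Replicates
are averaged after per-million normalization before calling.

**Peak–TSS association** uses a bidirectional 500 bp distance from the TSS
point to the nearest peak edge (0 inside a peak). The 5'-only window
appears only in the feature partition; both constants are configurable
because the two conventions serve different questions. Gene-body marks use
a different rule — peaks covering > 20 % of the gene body — because a body
mark has no single summit; the threshold is a declared default, not a
published value.

**Broad domains** are merged broad peaks (merge gap 1 kb, chosen to bridge
single depleted bins inside otherwise continuous regions). A gene is *in* a
domain when strictly more than half its body is covered. Border proximity
to the pooled TSS/TES point set is tested against `n_anchor_draws` sets of
uniform random anchors (equally many per draw as observed borders, no
mappability mask) with a two-sided rank-sum test; borders are measured at
the outermost enriched bin edge. Generation uniqueness of long domains uses
any-overlap (≥ 1 bp) by default, with a reciprocal-overlap variant by
argument.

**Chromatin states.** Sixteen states enumerate presence/absence of
H3K4me2, H3K4me3, H3K9ac, H3K27ac; ids order subsets by descending mark
count, ties by the canonical mark order, so state 1 = all four and state
16 = none. Only state 1 is externally anchored; the rest of the numbering
is this package's declaration, and no correspondence with any published
key is claimed. The built-in differential-expression test (Welch on
log2(TPM+1), BH) is a stand-in; an externally computed DE table takes
precedence when supplied. "Fold change > 2" is applied on the linear scale
(|log2FC| > 1), two-sided; gain-concordance counts *net* mark gain in the
biased generation (strict-superset variant by flag).

**NDR detection** is threshold-based because no published procedure
exists to copy: bins below `depth_threshold` (default 0.5) times the local
background (median MNase signal over a 5 kb window centred on the queried
region) form maximal runs; a shared NDR spans both TSSs of a divergent
pair within one bin. Detection is scale-invariant by construction. "Gene 2"
of a pair is the right-hand gene in scaffold coordinates.

## The synthetic world

The generator plants, at desk scale, the structure the analyses assume.
Defaults (the stated world):

| parameter | default | basis |
|---|---|---|
| genome | 2 scaffolds × 1 Mb, 1000 genes, 50 bp bins | desk scale; every test finishes in minutes |
| divergent-flanking target | 0.62 | published census (61.7 %) |
| intergenic medians (div/tan/conv) | 409 / 2293 / 409 bp (log-normal) | published medians for divergent and tandem; convergent unstated, set to the divergent scale so the stated gene count fits the stated genome |
| gene model | geometric(0.5)+... exons, exon median 150 bp, intron median 110 bp, min body 350 bp | sized analytically so 1000 genes plus paper-scale gaps fit 2 Mb; the body minimum keeps convergent TSSs from sitting inside one another's TSS chromatin region, an artefact real ~7 kb genes never show |
| TSS marks | amplitude 50–60 reads/bin, Gaussian sd 100 bp (double peak: offset 150, sd 75), presence 0.78–0.80, coupling 0.3 on log1p(TPM) | presence matches the published 77–83 % association; the double peak flanks the NDR at nucleosome scale; log-linear coupling is the simplest monotone form behind the published decile profiles |
| broad domains | runs of ~2.2 consecutive genes, borders at gene ends jittered N(0, 200 bp), coverage target 0.372, spacing ≥ 2.5 kb | published 37.2 % coverage and multi-gene domains; spacing keeps planted domains separable at the 1 kb merge scales |
| GBGs | 4 % of genes, SP share 0.65, \|log2FC\| = 1.05 + Exp(3.1 SP / 1.75 GA), lncRNA weight 3×, adjacent co-regulation 0.84 | published 4 %, 503/774 SP share, mean fold changes 4.2/2.8, lncRNA enrichment and 84 % co-direction |
| GBG state rule | off-generation per-mark presence 0.7; biased generation jumps to state 1 with p 0.748 (SP) / 0.264 (GA), otherwise gains each missing mark with p 0.6 | published transition-to-state-1 asymmetry; gains-only construction makes concordance 1 by design |
| repression | genes > 50 % inside a domain −1 log2; genes overlapping a marked transposon −1 log2, additive | published association of both marks with reduced expression; magnitude unstated, 2-fold is a moderate choice |
| MNase / NDR | plateau 400 reads/bin; dips depth 0.6, width 150 bp; divergent gaps < 600 bp share one NDR | published shared-NDR scale (~600 bp) and mononucleosome fragment sizes; the deep plateau reflects deep MNase libraries and keeps threshold runs contiguous under Poisson noise |
| noise | Poisson per bin (ChIP background 20 reads/bin); replicate TPM noise log2-sd 0.005; 2 replicates per generation | two biological replicates as published; see limitations for the noise level |

Shared TSS regions: divergent pairs with gaps under 600 bp share their
TSS-mark truth status (and follow a GBG member's per-generation marks) —
the planted counterpart of the observation that such pairs share one
chromatin domain.

The planted within-pair expression correlation is stated on the measured
scale (Pearson of log2(TPM+1)); the generator inverts the attenuation of
that transform with Gauss–Hermite quadrature to find the latent Gaussian
copula parameter, so recovery tests compare like with like.

**What the generator does *not* emulate:** read-level sampling (fragment
lengths, duplicates, mappability), sequence content (no FASTA), spatial
autocorrelation of marks beyond domains, antisense transcription,
generation-specific domains (the two generations share one planted domain
set by default), and real biological replicate dispersion. A green
recovery test therefore establishes that the estimators are consistent
with their own stated model at realistic effect sizes — not that they
would perform identically on read-level data.

## Numerical and design choices

* Wilcoxon rank-sum: exact enumeration for tie-free samples up to n = 25
  per group, normal approximation with tie correction otherwise; two-sided
  throughout; an all-tied comparison returns p = 1 directly.
* Identical zero-variance groups in the Welch stand-in return p = 1 (no
  evidence) rather than NaN.
* BH/Bonferroni go through `statsmodels.multipletests` and are verified
  against brute-force oracles in the tests.
* Rebinning distributes record mass by overlap length, exactly conserving
  ∑ value × length; final partial bins keep their true width.
* Peak scores are −log10 of the best adjusted p in the peak, capped at
  300; summits are the midpoint of the most control-enriched bin.
* `TSS-adjacent intergenic regions` are divergent plus tandem gaps
  (convergent gaps touch two TESs); pairs with overlapping gene bodies get
  length 0 and a flag; all annotated biotypes enter the pair census.
* Scaffold layouts redraw up to 50 times when a draw overflows the
  scaffold, then fail with the required length; with the default models
  the expected usage is ~87 % of the scaffold, so redraws are rare.

## Known limitations

* **Replicate-noise ceiling.** With two replicates the Welch test has ~2
  degrees of freedom, capping attainable p-values near 1/t²; at a 4 %
  planted prevalence over 1000 genes the BH cutoff is ~2 × 10⁻³, so
  recovery at sensitivity ≥ 0.8 is only possible at near-technical
  replicate noise. The default (log2-sd 0.005) was fixed by a power
  simulation before the tests were written; at biologically realistic
  noise (log2-sd ≥ 0.05) two replicates cannot support these thresholds —
  a property of the design, not of the implementation.
* The toy world's fraction of biased genes that keep their chromatin state
  (~0.3) is lower than real-data values (~0.6): the off-generation
  presence model is deliberately simple and not calibrated to that
  statistic.
* The Yates-corrected chi-square is conservative and its p-values are
  discrete on small tables; its null calibration is asserted as type-I
  control at 5 %, not as exact uniformity.
* The border null has no mappability or gap mask, matching the uniform
  random anchors it stands in for.
* Absolute counts from the published experiment (e.g. total biased genes,
  Mbp of domain coverage) require the original data deposit and genome
  annotation; they are inputs to one acceptance check that is necessarily
  red when the reference annotation is not present locally.
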