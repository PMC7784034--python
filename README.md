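# chromcycle

Chromatin-landscape analysis for histone-mark ChIP-seq across the two
generations of a haploid-diploid life cycle, plus a seeded synthetic-data
generator that makes every stage testable end to end at desk scale.

Brown algae such as *Ectocarpus* alternate between a sporophyte (SP) and a
gametophyte (GA) generation. Genome-wide histone post-translational
modification (PTM) profiles in such systems show TSS-localised activation
marks (H3K4me2/3, H3K9ac, H3K14ac, H3K27ac), a gene-body elongation mark
(H3K36me3), a transposon-associated mark (H4K20me3) and broad multi-gene
H3K79me2 domains. `chromcycle` re-implements the downstream analyses of
such an experiment for people who have mapped coverage and annotation in
hand: genome feature partitioning, peak calling and peak-to-TSS
association, broad-domain segmentation with a randomized border statistic,
combinatorial chromatin states and their transitions at generation-biased
genes, and divergent gene-pair promoter analysis.

## The statistics at the core

* **Peak calling** (stand-in for a read-level caller): per 50-bp bin
  *x<sub>i</sub>*, a Poisson tail test against
  λ<sub>i</sub> = max(λ<sub>global</sub>, λ<sub>10 kb</sub>) estimated from
  the input control and scaled for library size; Benjamini–Hochberg over
  bins at FDR 0.01; significant bins merged (gap ≤ 1 bin narrow / 1 kb
  broad).
* **Broad domains**: merged broad peaks; a gene is "in" a domain when
  > 50 % of its body (TSS–TES) lies inside. Domain **borders** are tested
  for proximity to the nearest TSS-or-TES point against `n` draws of
  uniform random anchors (two-sided Wilcoxon rank-sum of observed vs pooled
  null distances).
* **Chromatin states**: the 16 presence/absence combinations of H3K4me2,
  H3K4me3, H3K9ac and H3K27ac at a gene's TSS (presence = peak within
  500 bp). State 1 = all four present. Transitions at generation-biased
  genes are summarised by gain-concordance, per-bias fraction of
  transitions into state 1 (two-proportion z) and a Wilcoxon on |log2FC|.
* **Generation-biased genes (GBGs)**: TPM<sub>i</sub> = 10⁶ (c<sub>i</sub>/L<sub>i</sub>) / Σ<sub>j</sub>(c<sub>j</sub>/L<sub>j</sub>);
  log2FC = log2((TPM̄<sub>SP</sub>+0.5)/(TPM̄<sub>GA</sub>+0.5)); Welch test on
  log2(TPM+1) with BH adjustment; a GBG passes padj < 0.05, fold > 2 and
  TPM > 1 with a consistent direction in every experiment.
* **Divergent pairs**: adjacent genes on opposite strands transcribed apart;
  intergenic lengths, TSS-window signal by orientation, shared
  nucleosome-depleted regions (NDRs) from MNase coverage (bins below half
  the local background median), and within-pair Pearson correlation of
  log2(TPM+1).

## Worked example

```python
import chromcycle as cc

ds = cc.generate_dataset(seed=1)               # 2 x 1 Mb, 1000 genes
pairs = cc.classify_adjacent_pairs(ds.annotation)
print(round(cc.divergent_flanking_fraction(pairs), 3))
stats = cc.pair_length_stats(pairs)
print(stats["medians"])

track = cc.average_tracks(ds.replicate_tracks("H3K4me3", "sp"))
peaks = cc.call_peaks(track, ds.input_tracks["sp"], "narrow")
print(round(cc.tss_presence(peaks, ds.annotation.genes)["fraction"], 3))
```

prints

```
0.63
{'divergent': 423.0, 'tandem': 2397.0, 'convergent': 423.0}
0.808
```

i.e. 63 % of genes flanking TSS-adjacent intergenic regions sit in a
divergent pair, divergent gaps are about 5–6× shorter than tandem gaps
(medians 423 vs 2397 bp), and an H3K4me3 peak falls within 500 bp of the
TSS for 80.8 % of genes — the structure the generator plants and the
analyses recover.

The same pipeline is available from the shell:

```bash
chromcycle simulate --outdir data --seed 1
chromcycle features --annotation data/genes.gff3 --te data/te.bed --outdir out/features --seed 1
chromcycle peaks    --annotation data/genes.gff3 --tracks data/tracks \
                    --control data/tracks/input_sp.bedGraph --outdir out/peaks --seed 1
chromcycle domains  --annotation data/genes.gff3 \
                    --broadpeaks out/peaks/H3K79me2_sp_peaks.bed --outdir out/domains --seed 1
chromcycle states   --annotation data/genes.gff3 --presence out/peaks/tss_presence.tsv \
                    --expression data/expression.tsv --de data/de.tsv --outdir out/states --seed 1
chromcycle pairs    --annotation data/genes.gff3 --tracks data/tracks \
                    --mnase data/tracks/mnase_sp.bedGraph \
                    --expression data/expression.tsv --outdir out/pairs --seed 1
chromcycle report   --indir out --outdir out/report --seed 1
```

## Acceptance script

`scripts/acceptance.py` regenerates the default synthetic world from the
given seed and runs the complete pipeline from scratch — feature partition
and pair census, peak calling with TSS association for every TSS mark,
broad-domain segmentation with the border permutation test, differential
expression and biased-gene calling, chromatin-state transitions, and the
shared-NDR and pair-correlation analyses — printing a stage-by-stage
summary and writing the result JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

`docs/methods.md` describes the model assumptions, every tunable parameter
with its default and rationale, what the synthetic generator does and does
not emulate, and known limitations.
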