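"""Seeded toy genome, expression and coverage generator with ground truth.

The generator realises, at desk scale (2 scaffolds x 1 Mb, 1000 genes,
50 bp bins), the statistical structure the downstream analyses assume:

* adjacent-gene orientation controlled by a two-state strand Markov chain —
  with flip probability q the fraction of genes belonging to a divergent
  pair is exactly q (triple enumeration), so q is set to the divergent
  target directly;
* orientation-dependent intergenic gaps (log-normal; divergent median
  409 bp, tandem 2293 bp);
* TSS-peaked marks whose amplitude couples log-linearly to expression, one
  double-peaked mark, a gene-body mark, a transposon mark and one broad
  multi-gene domain mark with borders snapped to gene ends;
* divergent pairs closer than ~600 bp share one TSS chromatin region: their
  TSS-mark status and a single nucleosome-depleted region are shared;
* ~4% generation-biased genes whose biased generation gains TSS marks, with
  a sporophyte/gametophyte asymmetry in transitions to the all-marked state;
* Poisson read noise per bin and an input (background-only) control.

Every random draw flows from one ``numpy`` SeedSequence, so identical
(config, seed) give byte-identical emitted datasets.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import genome_features
from .chromatin_states import STATE_MARKS, simple_de_test
from .io_formats import (ExpressionTable, Gene, GenomeAnnotation, Interval,
                         SignalTrack, write_annotation, write_de,
                         write_expression, write_intervals, write_track)

TSS_MARKS = ("H3K4me2", "H3K4me3", "H3K9ac", "H3K14ac", "H3K27ac")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class MarkModel:
    shape: str                      # tss_peak | tss_double_peak | gene_body |
                                    # te_peak | broad_domain
    amplitude: float = 50.0         # added mean reads per bin at the feature
    width: int = 100                # gaussian sd (bp) for peaked shapes
    offset: int = 0                 # half-distance of the double peak (bp)
    expression_coupling: float = 0.3  # slope on log1p(TPM)
    presence_rate: float = 0.8      # baseline per-gene truth presence


def default_mark_models() -> dict[str, MarkModel]:
    return {
        # double peak flanks the TSS nucleosome-depleted region (+1/-1
        # nucleosome scale), hence the 150 bp offset and tighter width
        "H3K4me2": MarkModel("tss_double_peak", 60, 75, 150, 0.3, 0.80),
        "H3K4me3": MarkModel("tss_peak", 60, 100, 0, 0.3, 0.80),
        "H3K9ac": MarkModel("tss_peak", 50, 100, 0, 0.3, 0.80),
        "H3K14ac": MarkModel("tss_peak", 50, 100, 0, 0.3, 0.78),
        "H3K27ac": MarkModel("tss_peak", 50, 100, 0, 0.3, 0.80),
        "H3K36me3": MarkModel("gene_body", 30, 0, 0, 0.3, 0.74),
        "H4K20me3": MarkModel("te_peak", 50, 150, 0, 0.0, 0.95),
        "H3K79me2": MarkModel("broad_domain", 30, 0, 0, 0.0, 1.0),
    }


@dataclass
class IntergenicModel:
    """Per-orientation log-normal gap models (median bp, sigma in ln space)."""

    divergent_median: float = 409.0
    divergent_sigma: float = 0.5
    tandem_median: float = 2293.0
    tandem_sigma: float = 0.4
    convergent_median: float = 409.0
    convergent_sigma: float = 0.5


@dataclass
class DomainModel:
    genes_per_domain_geom_p: float = 0.45   # genes per domain = 1 + Geom(p)
    border_jitter_sd: float = 200.0
    fraction_borders_at_tss_tes: float = 1.0
    coverage_target: float = 0.372
    min_spacing: int = 2500                 # keeps planted domains separable


@dataclass
class ExpressionModel:
    tpm_log2_median: float = math.log2(10)
    tpm_log2_sd: float = 2.0
    gbg_fraction: float = 0.04
    sp_bias_fraction: float = 0.65          # 503 of 774 biased genes
    fc_exp_mean_sp: float = 3.1             # |log2fc| = fc_min + Exp(mean)
    fc_exp_mean_ga: float = 1.75
    fc_min: float = 1.05
    replicates: int = 2
    replicate_log2_sd: float = 0.005
    pair_correlation: float = 0.0           # planted divergent-pair corr.
    lncrna_gbg_weight: float = 3.0
    adjacent_coregulation: float = 0.84
    # chromatin-state behaviour of generation-biased genes
    gbg_offgen_presence: float = 0.7
    sp_to_state1: float = 0.748
    ga_to_state1: float = 0.264
    gain_prob: float = 0.6
    # repression planted on genes inside broad domains (> 50% of body) and
    # genes whose body overlaps a marked transposon; additive when both
    domain_repression_log2: float = 1.0
    te_mark_repression_log2: float = 1.0


@dataclass
class NdrModel:
    depth: float = 0.6              # fractional dip below the MNase plateau
    width: int = 150                # bp around a lone TSS
    shared_threshold: int = 600     # divergent gaps below this share one NDR
    shared_flank: int = 75


@dataclass
class SyntheticConfig:
    n_scaffolds: int = 2
    scaffold_length: int = 1_000_000
    n_genes: int = 1000
    divergent_fraction_target: float = 0.62
    intergenic: IntergenicModel = field(default_factory=IntergenicModel)
    exon_count_geom_p: float = 0.5          # exons = Geom(p), mean 1/p
    exon_length_median: float = 150.0
    exon_length_sigma: float = 0.45
    intron_length_median: float = 110.0
    intron_length_sigma: float = 1.0
    # keeps gene bodies at least TSS-window scale so convergent TSSs are not
    # pushed inside one another's TSS chromatin region at desk scale
    min_gene_length: int = 350
    lncrna_fraction: float = 0.1
    te_per_100kb: float = 6.0
    te_intron_weight: float = 0.44          # paper: 44% of TEs in introns
    te_length_median: float = 500.0
    te_length_sigma: float = 0.25
    te_min_length: int = 400
    mark_models: dict[str, MarkModel] = field(default_factory=default_mark_models)
    domain: DomainModel = field(default_factory=DomainModel)
    expression: ExpressionModel = field(default_factory=ExpressionModel)
    ndr: NdrModel = field(default_factory=NdrModel)
    chip_background: float = 20.0           # mean reads per bin
    mnase_background: float = 400.0
    chip_replicates: int = 2
    poisson_noise: bool = True
    bin_size: int = 50

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for key, sub in (("intergenic", IntergenicModel), ("domain", DomainModel),
                         ("expression", ExpressionModel), ("ndr", NdrModel)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "mark_models" in d:
            d["mark_models"] = {
                k: (MarkModel(**v) if isinstance(v, dict) else v)
                for k, v in d["mark_models"].items()
            }
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests.

    ``presence[gen]`` is a gene x mark boolean frame (five TSS marks, the
    gene-body mark, and the TE mark as body-overlap with a marked TE);
    ``domains[gen]`` the planted broad intervals; ``gbgs`` the planted
    generation-biased genes (bias, log2fc, biotype); ``ndrs`` the planted
    nucleosome-depleted regions with their shared flag.
    """

    presence: dict[str, pd.DataFrame]
    domains: dict[str, list[Interval]]
    gbgs: pd.DataFrame
    ndrs: list[tuple[Interval, bool]]
    marked_tes: list[Interval]

    def to_json(self) -> dict:
        return {
            "presence": {g: {c: df[c].astype(bool).to_dict()
                             for c in df.columns}
                         for g, df in self.presence.items()},
            "domains": {g: [[d.scaffold, d.start, d.end] for d in ds]
                        for g, ds in self.domains.items()},
            "gbgs": self.gbgs.reset_index().to_dict(orient="records"),
            "ndrs": [[iv.scaffold, iv.start, iv.end, bool(s)]
                     for iv, s in self.ndrs],
            "marked_tes": [[t.scaffold, t.start, t.end] for t in self.marked_tes],
        }


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    seed: int
    annotation: GenomeAnnotation
    expression: ExpressionTable
    truth: GroundTruth
    tracks: dict[tuple[str, str, int], SignalTrack]
    input_tracks: dict[str, SignalTrack]
    mnase: dict[str, SignalTrack]

    def replicate_tracks(self, mark: str, generation: str) -> list[SignalTrack]:
        return [t for (m, g, _), t in sorted(self.tracks.items())
                if m == mark and g == generation]


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _lognormal(rng, median: float, sigma: float, size=None):
    return rng.lognormal(math.log(median), sigma, size)


def _copula_rho(target: float, log2_median: float, log2_sd: float) -> float:
    """Latent normal correlation that yields ``target`` Pearson r of
    log2(TPM+1) when log2 TPM ~ N(log2_median, log2_sd^2).

    Uses Gauss-Hermite quadrature for the moments of the transformed
    bivariate normal and a bisection on the latent correlation.
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(64)
    w = weights / weights.sum()

    def g(zv):
        return np.log2(2.0 ** (log2_median + log2_sd * zv) + 1.0)

    m1 = float(np.sum(w * g(nodes)))
    v1 = float(np.sum(w * (g(nodes) - m1) ** 2))

    def measured(rho: float) -> float:
        zx = nodes[:, None]
        zy = rho * zx + math.sqrt(max(1 - rho ** 2, 0.0)) * nodes[None, :]
        cov = np.sum(w[:, None] * w[None, :]
                     * (g(zx) - m1) * (g(zy) - m1))
        return float(cov / v1)

    lo, hi = 0.0, 1.0
    for _ in range(40):
        mid = (lo + hi) / 2
        if measured(mid) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def generate_annotation(config: SyntheticConfig,
                        rng: np.random.Generator) -> GenomeAnnotation:
    """Place non-overlapping genes with orientation-dependent gaps, then
    transposons in introns and intergenic space (never inside exons)."""
    scaffolds = {f"scaffold_{i + 1}": config.scaffold_length
                 for i in range(config.n_scaffolds)}
    per_scaffold = _allocate(config.n_genes, config.n_scaffolds)
    genes: list[Gene] = []
    gid = 0
    q = config.divergent_fraction_target
    ig = config.intergenic
    gap_model = {
        "divergent": (ig.divergent_median, ig.divergent_sigma),
        "tandem": (ig.tandem_median, ig.tandem_sigma),
        "convergent": (ig.convergent_median, ig.convergent_sigma),
    }
    for scaf, n in zip(scaffolds, per_scaffold):
        if n == 0:
            continue
        layout = None
        required = 0
        for _attempt in range(50):
            layout = _layout_scaffold(scaf, n, config, gap_model, q, rng)
            if layout is not None:
                break
            required = max(required, config.scaffold_length + 1)
        if layout is None:
            raise ValueError(
                f"genome too small for {config.n_genes} genes: scaffold "
                f"{scaf} of {config.scaffold_length} bp repeatedly overflowed "
                f"(needs at least {required} bp)")
        for exons, strand in layout:
            stranded = [Interval(scaf, e.start, e.end, strand) for e in exons]
            ordered = tuple(stranded if strand == "+" else stranded[::-1])
            biotype = ("lncRNA" if rng.random() < config.lncrna_fraction
                       else "protein_coding")
            gid += 1
            genes.append(Gene(
                f"gene_{gid:05d}",
                Interval(scaf, exons[0].start, exons[-1].end, strand),
                strand, ordered, biotype))
    tes = _place_tes(scaffolds, genes, config, rng)
    return GenomeAnnotation(scaffolds, genes, tes)


def _layout_scaffold(scaf: str, n: int, config: SyntheticConfig, gap_model,
                     q: float, rng: np.random.Generator):
    """One attempted gene layout; None when the draw overflows the scaffold."""
    ig = config.intergenic
    strands = ["+" if rng.random() < 0.5 else "-"]
    for _ in range(n - 1):
        prev = strands[-1]
        strands.append({"+": "-", "-": "+"}[prev] if rng.random() < q else prev)
    pos = int(_lognormal(rng, ig.tandem_median, ig.tandem_sigma))
    layout = []
    for i in range(n):
        if i > 0:
            prev, cur = strands[i - 1], strands[i]
            orient = ("divergent" if (prev, cur) == ("-", "+") else
                      "convergent" if (prev, cur) == ("+", "-") else "tandem")
            med, sig = gap_model[orient]
            pos += max(int(_lognormal(rng, med, sig)), 2)
        n_exons = int(rng.geometric(config.exon_count_geom_p))
        exon_lens = np.maximum(_lognormal(
            rng, config.exon_length_median, config.exon_length_sigma,
            n_exons).astype(int), 20)
        intron_lens = np.maximum(_lognormal(
            rng, config.intron_length_median, config.intron_length_sigma,
            max(n_exons - 1, 0)).astype(int), 20)
        exons, cursor = [], pos
        for k in range(n_exons):
            exons.append(Interval(scaf, cursor, cursor + int(exon_lens[k])))
            cursor = exons[-1].end
            if k < n_exons - 1:
                cursor += int(intron_lens[k])
        if exons[-1].end - pos < config.min_gene_length:
            grow = config.min_gene_length - (exons[-1].end - pos)
            last = exons[-1]
            exons[-1] = Interval(scaf, last.start, last.end + grow)
        end = exons[-1].end
        if end > config.scaffold_length:
            return None
        layout.append((exons, strands[i]))
        pos = end
    return layout


def _allocate(total: int, parts: int) -> list[int]:
    base = total // parts
    out = [base] * parts
    for i in range(total - base * parts):
        out[i] += 1
    return out


def _place_tes(scaffolds, genes, config: SyntheticConfig,
               rng: np.random.Generator) -> list[Interval]:
    n_te = int(round(config.te_per_100kb * sum(scaffolds.values()) / 1e5))
    introns = []
    for g in genes:
        exons = sorted(g.exons, key=lambda e: e.start)
        for a, b in zip(exons, exons[1:]):
            if b.start - a.end >= config.te_min_length + 40:
                introns.append(Interval(g.scaffold, a.end, b.start))
    intergenics = []
    for scaf in scaffolds:
        sg = [g for g in genes if g.scaffold == scaf]
        bounds = [0] + [x for g in sg for x in (g.interval.start, g.interval.end)] \
            + [scaffolds[scaf]]
        for s, e in zip(bounds[0::2], bounds[1::2]):
            if e - s >= config.te_min_length + 40:
                intergenics.append(Interval(scaf, s, e))
    tes, used = [], []
    for _ in range(n_te):
        length = max(int(_lognormal(rng, config.te_length_median,
                                    config.te_length_sigma)),
                     config.te_min_length)
        pool = introns if rng.random() < config.te_intron_weight else intergenics
        placed = False
        for _ in range(20):
            if not pool:
                break
            host = pool[rng.integers(len(pool))]
            if len(host) < length + 40:
                continue
            s = int(rng.integers(host.start + 20, host.end - length - 20 + 1))
            iv = Interval(host.scaffold, s, s + length)
            if any(iv.overlap(u) for u in used if u.scaffold == iv.scaffold):
                continue
            tes.append(iv)
            used.append(iv)
            placed = True
            break
        if not placed and pool is introns:
            pool = intergenics  # fall back when no intron fits
    return tes


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(annotation: GenomeAnnotation, config: SyntheticConfig,
                        rng: np.random.Generator,
                        domains: list[Interval] | None = None,
                        marked_tes: list[Interval] | None = None,
                        ) -> tuple[ExpressionTable, pd.DataFrame]:
    """Log-normal baseline TPM, planted generation-biased genes and
    replicate columns for both generations.

    When planted domains / marked transposons are supplied, genes more than
    half inside a domain and genes overlapping a marked transposon are
    repressed by the configured log2 amounts (additively when both apply).
    Planted biased genes are guaranteed to survive the calling filters in
    the noiseless limit (padj aside): baseline above the TPM threshold and a
    fold change that clears the pseudocounted log2fc threshold.
    """
    em = config.expression
    if em.replicates < 2:
        raise ValueError("differential expression needs >= 2 replicates")
    ids = annotation.gene_ids
    n = len(ids)
    z = rng.normal(size=n)
    if em.pair_correlation > 0 and n:
        pairs = genome_features.classify_adjacent_pairs(annotation)
        index = {g: i for i, g in enumerate(ids)}
        # pair_correlation is stated on the measured scale, Pearson r of
        # log2(TPM+1); invert the attenuation of that transform to get the
        # latent Gaussian-copula correlation
        rho = _copula_rho(em.pair_correlation, em.tpm_log2_median,
                          em.tpm_log2_sd)
        for p in pairs:
            if p.orientation == "divergent":
                i, j = index[p.left.id], index[p.right.id]
                z[j] = rho * z[i] + math.sqrt(1 - rho ** 2) * rng.normal()
    base = 2.0 ** (em.tpm_log2_median + em.tpm_log2_sd * z)

    if domains is not None and em.domain_repression_log2 > 0:
        for k, g in enumerate(annotation.genes):
            ov = sum(g.interval.overlap(d) for d in domains
                     if d.scaffold == g.scaffold)
            if ov > 0.5 * g.length:
                base[k] *= 2.0 ** -em.domain_repression_log2
    if marked_tes is not None and em.te_mark_repression_log2 > 0:
        for k, g in enumerate(annotation.genes):
            if any(g.interval.overlap(t) > 0 for t in marked_tes):
                base[k] *= 2.0 ** -em.te_mark_repression_log2

    biotypes = np.array([annotation.gene(g).biotype for g in ids])
    weights = np.where(biotypes == "lncRNA", em.lncrna_gbg_weight, 1.0)
    weights[base <= 1.0] = 0.0  # plant only genes that can pass the TPM filter
    n_gbg = min(int(rng.binomial(n, em.gbg_fraction)), int((weights > 0).sum()))
    gbg_idx = (rng.choice(n, size=n_gbg, replace=False,
                          p=weights / weights.sum())
               if n_gbg else np.array([], dtype=int))
    bias = np.where(rng.random(n_gbg) < em.sp_bias_fraction, "sp", "ga")

    # adjacent lncRNA/coding co-regulation
    if n_gbg:
        pairs = genome_features.classify_adjacent_pairs(annotation)
        neighbour = {}
        for p in pairs:
            neighbour.setdefault(p.left.id, []).append(p.right.id)
            neighbour.setdefault(p.right.id, []).append(p.left.id)
        gbg_ids = [ids[i] for i in gbg_idx]
        bias_of = dict(zip(gbg_ids, bias))
        for k, g in enumerate(gbg_ids):
            if biotypes[gbg_idx[k]] != "lncRNA":
                continue
            partners = [x for x in neighbour.get(g, ())
                        if x in bias_of and annotation.gene(x).biotype
                        == "protein_coding"]
            if partners and rng.random() < em.adjacent_coregulation:
                bias[k] = bias_of[partners[0]]
        bias_of = dict(zip(gbg_ids, bias))

    fc = np.empty(n_gbg)
    for k in range(n_gbg):
        scale = em.fc_exp_mean_sp if bias[k] == "sp" else em.fc_exp_mean_ga
        b = base[gbg_idx[k]]
        while True:
            f = em.fc_min + rng.exponential(scale)
            if math.log2((b * 2 ** f + 0.5) / (b + 0.5)) > 1.0:
                fc[k] = f
                break

    sp_mean, ga_mean = base.copy(), base.copy()
    for k, i in enumerate(gbg_idx):
        (sp_mean if bias[k] == "sp" else ga_mean)[i] *= 2.0 ** fc[k]

    cols, data = [], []
    for gen, mean in (("sp", sp_mean), ("ga", ga_mean)):
        for r in range(1, em.replicates + 1):
            cols.append(f"{gen}_rep{r}")
            noise = (rng.normal(0, em.replicate_log2_sd, n)
                     if em.replicate_log2_sd > 0 else np.zeros(n))
            data.append(mean * 2.0 ** noise)
    tpm = pd.DataFrame(np.column_stack(data), index=pd.Index(ids, name="gene_id"),
                       columns=cols)
    generations = {c: c.split("_")[0] for c in cols}
    signed = np.where(bias == "sp", fc, -fc)
    gbgs = pd.DataFrame({
        "bias": bias, "log2fc": signed,
        "biotype": biotypes[gbg_idx],
    }, index=pd.Index([ids[i] for i in gbg_idx], name="gene_id")).sort_index()
    return ExpressionTable(tpm, generations), gbgs


# ---------------------------------------------------------------------------
# mark presence, domains, NDRs
# ---------------------------------------------------------------------------

def _assign_presence(annotation: GenomeAnnotation, gbgs: pd.DataFrame,
                     config: SyntheticConfig, rng: np.random.Generator,
                     marked_tes: list[Interval]) -> dict[str, pd.DataFrame]:
    em = config.expression
    ids = annotation.gene_ids
    marks = [m for m, mm in config.mark_models.items()
             if mm.shape in ("tss_peak", "tss_double_peak", "gene_body")]
    baseline = pd.DataFrame(
        {m: rng.random(len(ids)) < config.mark_models[m].presence_rate
         for m in marks}, index=pd.Index(ids, name="gene_id"))

    # shared TSS chromatin region of close divergent pairs
    pairs = genome_features.classify_adjacent_pairs(annotation)
    gbg_set = set(gbgs.index)
    tss_marks = [m for m in marks if config.mark_models[m].shape.startswith("tss")]
    shared_pairs = [
        p for p in pairs
        if (p.orientation == "divergent" and not p.overlapping
            and p.length < config.ndr.shared_threshold)
    ]
    for p in shared_pairs:
        if p.left.id not in gbg_set and p.right.id not in gbg_set:
            baseline.loc[p.right.id, tss_marks] = baseline.loc[p.left.id, tss_marks]

    presence = {"sp": baseline.copy(), "ga": baseline.copy()}
    for gid, row in gbgs.iterrows():
        b = row["bias"]
        off = "ga" if b == "sp" else "sp"
        off_set = {m: bool(rng.random() < em.gbg_offgen_presence)
                   for m in tss_marks}
        p1 = em.sp_to_state1 if b == "sp" else em.ga_to_state1
        if rng.random() < p1:
            on_set = {m: True for m in tss_marks}
        else:
            on_set = {m: (off_set[m] or rng.random() < em.gain_prob)
                      for m in tss_marks}
        for m in tss_marks:
            presence[off].loc[gid, m] = off_set[m]
            presence[b].loc[gid, m] = on_set[m]

    # a non-GBG member of a shared TSS region follows its GBG partner's
    # per-generation marks (the pair shares one chromatin domain)
    for p in shared_pairs:
        members = (p.left.id, p.right.id)
        flags = [m in gbg_set for m in members]
        if flags[0] != flags[1]:
            gbg_member = members[0] if flags[0] else members[1]
            partner = members[1] if flags[0] else members[0]
            for gen in presence:
                presence[gen].loc[partner, tss_marks] = \
                    presence[gen].loc[gbg_member, tss_marks]

    # TE mark presence per gene: body overlap with a marked transposon
    for gen in presence:
        hits = []
        for g in annotation.genes:
            hits.append(any(g.interval.overlap(t) > 0 for t in marked_tes))
        presence[gen]["H4K20me3"] = hits
    return presence


def _plant_domains(annotation: GenomeAnnotation, config: SyntheticConfig,
                   rng: np.random.Generator) -> list[Interval]:
    dm = config.domain
    domains: list[Interval] = []
    for scaf, length in annotation.scaffolds.items():
        genes = annotation.genes_on(scaf)
        covered, last_end, i = 0, -dm.min_spacing, 0
        while i < len(genes):
            g = genes[i]
            if (g.interval.start - last_end < dm.min_spacing
                    or covered >= dm.coverage_target * max(g.interval.start, 1)):
                i += 1
                continue
            k = int(rng.geometric(dm.genes_per_domain_geom_p))
            j = min(i + k - 1, len(genes) - 1)
            start = genes[i].interval.start
            end = genes[j].interval.end
            prev_end = genes[i - 1].interval.end if i > 0 else 0
            next_start = (genes[j + 1].interval.start if j + 1 < len(genes)
                          else length)
            if rng.random() >= dm.fraction_borders_at_tss_tes and prev_end < start:
                start = int(rng.integers(prev_end, start))
            if rng.random() >= dm.fraction_borders_at_tss_tes and end < next_start:
                end = int(rng.integers(end, next_start))
            if dm.border_jitter_sd > 0:
                start += int(rng.normal(0, dm.border_jitter_sd))
                end += int(rng.normal(0, dm.border_jitter_sd))
            start = max(max(start, last_end + dm.min_spacing // 2), 0)
            end = min(end, length)
            if end - start >= config.bin_size:
                domains.append(Interval(scaf, start, end))
                covered += end - start
                last_end = end
            i = j + 1
    return domains


def _plant_ndrs(annotation: GenomeAnnotation,
                config: SyntheticConfig) -> list[tuple[Interval, bool]]:
    nm = config.ndr
    pairs = genome_features.classify_adjacent_pairs(annotation)
    shared_tss: set[int] = set()
    ndrs: list[tuple[Interval, bool]] = []
    for p in pairs:
        if (p.orientation == "divergent" and not p.overlapping
                and p.length <= nm.shared_threshold):
            lo, hi = p.left.tss, p.right.tss
            ndrs.append((Interval(p.left.scaffold,
                                  max(0, lo - nm.shared_flank),
                                  min(annotation.scaffolds[p.left.scaffold],
                                      hi + nm.shared_flank)), True))
            shared_tss.update((id(p.left), id(p.right)))
    covered = {g.id for p in pairs for g in (p.left, p.right)
               if p.orientation == "divergent" and not p.overlapping
               and p.length <= nm.shared_threshold}
    half = nm.width // 2
    for g in annotation.genes:
        if g.id in covered:
            continue
        ndrs.append((Interval(g.scaffold, max(0, g.tss - half),
                              min(annotation.scaffolds[g.scaffold], g.tss + half)),
                     False))
    return ndrs


# ---------------------------------------------------------------------------
# coverage tracks
# ---------------------------------------------------------------------------

def _add_bump(arr: np.ndarray, bin_size: int, center: int, amp: float, sd: float,
              length: int) -> None:
    lo = max(0, int((center - 4 * sd) // bin_size))
    hi = min(len(arr) - 1, int((center + 4 * sd) // bin_size))
    if hi < lo:
        return
    x = (np.arange(lo, hi + 1) * bin_size + bin_size / 2)
    arr[lo:hi + 1] += amp * np.exp(-0.5 * ((x - center) / sd) ** 2)


def _add_plateau(arr: np.ndarray, bin_size: int, start: int, end: int,
                 amp: float) -> None:
    i0, i1 = start // bin_size, max((end - 1) // bin_size + 1, start // bin_size + 1)
    arr[i0:min(i1, len(arr))] += amp


def mark_transposons(annotation: GenomeAnnotation, config: SyntheticConfig,
                     rng: np.random.Generator) -> list[Interval]:
    """Transposons carrying the TE mark (per-TE presence draw)."""
    te_model = next((m for m, mm in config.mark_models.items()
                     if mm.shape == "te_peak"), None)
    if te_model is None:
        return []
    rate = config.mark_models[te_model].presence_rate
    return [t for t in annotation.tes if rng.random() < rate]


def simulate_tracks(annotation: GenomeAnnotation, expression: ExpressionTable,
                    gbgs: pd.DataFrame, config: SyntheticConfig,
                    rng: np.random.Generator,
                    domain_ivs: list[Interval] | None = None,
                    marked_tes: list[Interval] | None = None):
    """Build per-mark/generation/replicate coverage plus input and MNase
    tracks, and the ground-truth record they realise.

    Planted domains and marked transposons may be supplied (so expression
    repression and coverage share one truth); otherwise they are drawn here.
    """
    bs = config.bin_size
    scaffolds = dict(annotation.scaffolds)

    if marked_tes is None:
        marked_tes = mark_transposons(annotation, config, rng)
    if domain_ivs is None:
        domain_ivs = _plant_domains(annotation, config, rng)

    presence = _assign_presence(annotation, gbgs, config, rng, marked_tes)
    domains = {"sp": list(domain_ivs), "ga": list(domain_ivs)}
    ndrs = _plant_ndrs(annotation, config)
    truth = GroundTruth(presence, domains, gbgs, ndrs, marked_tes)

    def empty():
        return {s: np.zeros(math.ceil(l / bs)) for s, l in scaffolds.items()}

    tracks: dict[tuple[str, str, int], SignalTrack] = {}
    mean_tpm = {g: expression.mean_tpm(g) for g in ("sp", "ga")}
    for mark, mm in config.mark_models.items():
        for gen in ("sp", "ga"):
            mean = empty()
            for s in mean:
                mean[s] += config.chip_background
            if mm.shape in ("tss_peak", "tss_double_peak", "gene_body"):
                flags = presence[gen][mark]
                tpm = mean_tpm[gen]
                for g in annotation.genes:
                    if not flags[g.id]:
                        continue
                    amp = mm.amplitude * (
                        1 + mm.expression_coupling * math.log1p(max(tpm[g.id], 0)))
                    arr = mean[g.scaffold]
                    if mm.shape == "tss_peak":
                        _add_bump(arr, bs, g.tss, amp, mm.width,
                                  scaffolds[g.scaffold])
                    elif mm.shape == "tss_double_peak":
                        for c in (g.tss - mm.offset, g.tss + mm.offset):
                            _add_bump(arr, bs, c, amp, mm.width,
                                      scaffolds[g.scaffold])
                    else:
                        _add_plateau(arr, bs, g.interval.start, g.interval.end,
                                     amp)
            elif mm.shape == "te_peak":
                for t in marked_tes:
                    _add_plateau(mean[t.scaffold], bs, t.start, t.end,
                                 mm.amplitude)
            elif mm.shape == "broad_domain":
                for d in domains[gen]:
                    _add_plateau(mean[d.scaffold], bs, d.start, d.end,
                                 mm.amplitude)
            else:
                raise ValueError(f"unknown mark shape {mm.shape!r}")
            for rep in range(1, config.chip_replicates + 1):
                values = {
                    s: (rng.poisson(v).astype(float) if config.poisson_noise
                        else v.copy())
                    for s, v in mean.items()
                }
                tracks[(mark, gen, rep)] = SignalTrack(
                    bs, scaffolds, values, mark, gen, rep)

    input_tracks = {}
    for gen in ("sp", "ga"):
        flat = {s: np.full(math.ceil(l / bs), config.chip_background)
                for s, l in scaffolds.items()}
        values = {s: (rng.poisson(v).astype(float) if config.poisson_noise
                      else v.copy()) for s, v in flat.items()}
        input_tracks[gen] = SignalTrack(bs, scaffolds, values, "input", gen, 1)

    mnase = {}
    for gen in ("sp", "ga"):
        mean = {s: np.full(math.ceil(l / bs), config.mnase_background)
                for s, l in scaffolds.items()}
        for iv, _shared in ndrs:
            i0, i1 = iv.start // bs, max((iv.end - 1) // bs + 1, iv.start // bs + 1)
            mean[iv.scaffold][i0:i1] *= (1 - config.ndr.depth)
        values = {s: (rng.poisson(v).astype(float) if config.poisson_noise
                      else v.copy()) for s, v in mean.items()}
        mnase[gen] = SignalTrack(bs, scaffolds, values, "mnase", gen, 1)

    return tracks, input_tracks, mnase, truth


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def generate_dataset(config: SyntheticConfig | None = None,
                     seed: int = 1) -> SyntheticDataset:
    """Generate the complete dataset from one seed (deterministic)."""
    config = config if config is not None else SyntheticConfig()
    ss = np.random.SeedSequence(seed)
    r_ann, r_plant, r_expr, r_tracks = (np.random.default_rng(s)
                                        for s in ss.spawn(4))
    annotation = generate_annotation(config, r_ann)
    marked_tes = mark_transposons(annotation, config, r_plant)
    domain_ivs = _plant_domains(annotation, config, r_plant)
    expression, gbgs = simulate_expression(annotation, config, r_expr,
                                           domain_ivs, marked_tes)
    tracks, input_tracks, mnase, truth = simulate_tracks(
        annotation, expression, gbgs, config, r_tracks, domain_ivs, marked_tes)
    return SyntheticDataset(config, seed, annotation, expression, truth,
                            tracks, input_tracks, mnase)


def emit_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write the dataset as plain-text files: GFF3, TE BED, bedGraph tracks,
    expression/DE TSVs, truth.json and a config echo."""
    os.makedirs(outdir, exist_ok=True)
    tdir = os.path.join(outdir, "tracks")
    os.makedirs(tdir, exist_ok=True)
    write_annotation(dataset.annotation, os.path.join(outdir, "genes.gff3"))
    write_intervals(dataset.annotation.tes, os.path.join(outdir, "te.bed"))
    write_expression(dataset.expression, os.path.join(outdir, "expression.tsv"))
    write_de(simple_de_test(dataset.expression), os.path.join(outdir, "de.tsv"))
    for (mark, gen, rep), track in sorted(dataset.tracks.items()):
        write_track(track, os.path.join(tdir, f"{mark}_{gen}_rep{rep}.bedGraph"))
    for gen, track in sorted(dataset.input_tracks.items()):
        write_track(track, os.path.join(tdir, f"input_{gen}.bedGraph"))
    for gen, track in sorted(dataset.mnase.items()):
        write_track(track, os.path.join(tdir, f"mnase_{gen}.bedGraph"))
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(dataset.truth.to_json(), fh, indent=1, sort_keys=True)
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump({"seed": dataset.seed, **dataset.config.to_dict()}, fh,
                       sort_keys=True)
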