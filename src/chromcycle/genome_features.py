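"""Genome feature partitioning, adjacent gene-pair classification and the
shared statistical-test primitives.

The partition assigns every bp of every scaffold to exactly one of six
classes: the 500 bp window 5' of each TSS, first exons, other exons, first
introns, other introns, and intergenic space.  Intergenic, first-intron and
intron bp are additionally split by transposon overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import Gene, GenomeAnnotation, Interval

# partition class codes, in increasing priority (later codes win collisions)
INTERGENIC, INTRON, FIRST_INTRON, EXON, FIRST_EXON, UPSTREAM = range(6)
CLASS_NAMES = {
    INTERGENIC: "intergenic",
    INTRON: "intron",
    FIRST_INTRON: "first_intron",
    EXON: "exon",
    FIRST_EXON: "first_exon",
    UPSTREAM: "upstream_tss_500",
}
TE_SPLIT_CLASSES = (INTERGENIC, INTRON, FIRST_INTRON)


@dataclass
class FeatureClassMap:
    """Per-bp class codes plus a transposon-overlap mask, per scaffold."""

    classes: dict[str, np.ndarray]        # uint8 code arrays
    te_mask: dict[str, np.ndarray]        # bool arrays
    tss_window: int = 500

    def bp_totals(self, split_te: bool = True) -> dict[str, int]:
        """bp per class label; TE-eligible classes split into _te/_no_te."""
        out: dict[str, int] = {}
        for name, arr in self.classes.items():
            te = self.te_mask[name]
            for code, label in CLASS_NAMES.items():
                sel = arr == code
                if split_te and code in TE_SPLIT_CLASSES:
                    out[label + "_te"] = out.get(label + "_te", 0) + int((sel & te).sum())
                    out[label + "_no_te"] = out.get(label + "_no_te", 0) + int((sel & ~te).sum())
                else:
                    out[label] = out.get(label, 0) + int(sel.sum())
        return out

    def labels_in(self, interval: Interval) -> dict[str, int]:
        """bp of each class label inside an interval."""
        arr = self.classes[interval.scaffold][interval.start:interval.end]
        te = self.te_mask[interval.scaffold][interval.start:interval.end]
        out: dict[str, int] = {}
        for code in np.unique(arr):
            label = CLASS_NAMES[int(code)]
            sel = arr == code
            if code in TE_SPLIT_CLASSES:
                nte = int((sel & te).sum())
                if nte:
                    out[label + "_te"] = nte
                if int(sel.sum()) - nte:
                    out[label + "_no_te"] = int(sel.sum()) - nte
            else:
                out[label] = int(sel.sum())
        return out


@dataclass(frozen=True)
class GenePair:
    """Two genes adjacent on a scaffold and the gap between their bodies."""

    left: Gene
    right: Gene
    orientation: str                      # divergent | tandem | convergent
    intergenic: Interval | None           # None when gene bodies overlap
    length: int
    overlapping: bool = False


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...] = ()
    p_adjusted: float | None = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# feature partition
# ---------------------------------------------------------------------------

def build_feature_partition(annotation: GenomeAnnotation,
                            tss_window: int = 500) -> FeatureClassMap:
    """Partition every scaffold into the six feature classes.

    Collision priority (overlapping/nested genes):
    upstream > first_exon > exon > first_intron > intron > intergenic.
    The upstream window is truncated at the scaffold edge and at any
    neighbouring gene body.
    """
    classes = {n: np.zeros(l, dtype=np.uint8) for n, l in annotation.scaffolds.items()}
    body = {n: np.zeros(l, dtype=bool) for n, l in annotation.scaffolds.items()}
    for g in annotation.genes:
        body[g.scaffold][g.interval.start:g.interval.end] = True

    # paint in increasing priority so later classes overwrite earlier ones
    for code, selector in (
        (INTRON, lambda g: _introns(g)[1:]),
        (FIRST_INTRON, lambda g: _introns(g)[:1]),
        (EXON, lambda g: g.exons[1:]),
        (FIRST_EXON, lambda g: g.exons[:1]),
    ):
        for g in annotation.genes:
            for iv in selector(g):
                classes[g.scaffold][iv.start:iv.end] = code

    for g in annotation.genes:
        arr = classes[g.scaffold]
        occ = body[g.scaffold]
        length = annotation.scaffolds[g.scaffold]
        if g.strand == "+":
            lo = g.tss
            n = 0
            while n < tss_window and lo - 1 >= 0 and not occ[lo - 1]:
                lo -= 1
                n += 1
            arr[lo:g.tss] = UPSTREAM
        else:
            hi = g.tss
            n = 0
            while n < tss_window and hi < length and not occ[hi]:
                hi += 1
                n += 1
            arr[g.tss:hi] = UPSTREAM

    te_mask = {n: np.zeros(l, dtype=bool) for n, l in annotation.scaffolds.items()}
    for te in annotation.tes:
        te_mask[te.scaffold][te.start:te.end] = True
    return FeatureClassMap(classes, te_mask, tss_window)


def _introns(gene: Gene) -> list[Interval]:
    """Introns in 5'->3' order (gaps between consecutive exons)."""
    exons = sorted(gene.exons, key=lambda e: e.start)
    introns = [
        Interval(gene.scaffold, a.end, b.start)
        for a, b in zip(exons, exons[1:])
        if b.start > a.end
    ]
    return introns if gene.strand == "+" else introns[::-1]


# ---------------------------------------------------------------------------
# adjacent gene pairs
# ---------------------------------------------------------------------------

def classify_adjacent_pairs(annotation: GenomeAnnotation) -> list[GenePair]:
    """One pair per couple of genes adjacent on a scaffold.

    Orientation from the strands in scaffold order: (-, +) divergent,
    (+, -) convergent, same strand tandem.  The intergenic interval is the
    gap between gene bodies; overlapping bodies give length 0 and a flag.
    """
    pairs = []
    for scaf in annotation.scaffolds:
        genes = annotation.genes_on(scaf)
        for a, b in zip(genes, genes[1:]):
            if a.strand == "-" and b.strand == "+":
                orient = "divergent"
            elif a.strand == "+" and b.strand == "-":
                orient = "convergent"
            else:
                orient = "tandem"
            gap = b.interval.start - a.interval.end
            if gap > 0:
                pairs.append(GenePair(
                    a, b, orient, Interval(scaf, a.interval.end, b.interval.start), gap))
            else:
                pairs.append(GenePair(a, b, orient, None, 0, overlapping=True))
    return pairs


def divergent_flanking_fraction(pairs: list[GenePair]) -> float:
    """Fraction of genes flanking TSS-adjacent intergenic regions (divergent
    and tandem gaps) that belong to at least one divergent pair."""
    flanking: set[str] = set()
    in_divergent: set[str] = set()
    for p in pairs:
        if p.orientation in ("divergent", "tandem"):
            flanking.update((p.left.id, p.right.id))
        if p.orientation == "divergent":
            in_divergent.update((p.left.id, p.right.id))
    if not flanking:
        return float("nan")
    return len(flanking & in_divergent) / len(flanking)


def pair_length_stats(pairs: list[GenePair]) -> dict:
    """Median intergenic length per orientation plus a two-sided Wilcoxon
    rank-sum test of divergent vs tandem lengths."""
    lengths = {o: [p.length for p in pairs if p.orientation == o]
               for o in ("divergent", "tandem", "convergent")}
    medians = {o: (float(np.median(v)) if v else None) for o, v in lengths.items()}
    test = None
    if lengths["divergent"] and lengths["tandem"]:
        test = stat_test("wilcoxon", lengths["divergent"], lengths["tandem"])
    return {"medians": medians, "test": test,
            "n": {o: len(v) for o, v in lengths.items()}}


# ---------------------------------------------------------------------------
# statistical primitives
# ---------------------------------------------------------------------------

def stat_test(kind: str, *data) -> TestResult:
    """Shared test primitive.

    kinds: ``wilcoxon`` (two-sided Mann-Whitney rank-sum; exact enumeration
    for small tie-free samples, normal approximation with tie correction
    otherwise), ``chi2_yates`` (2x2 Pearson chi-square with Yates
    continuity), ``two_proportion_z`` (pooled two-sided z), ``pearson``,
    ``spearman``.
    """
    if kind == "wilcoxon":
        x, y = np.asarray(data[0], float), np.asarray(data[1], float)
        if len(x) == 0 or len(y) == 0:
            raise ValueError("wilcoxon needs two non-empty samples")
        pooled = np.concatenate([x, y])
        if np.all(pooled == pooled[0]):
            return TestResult(len(x) * len(y) / 2, 1.0, "wilcoxon", (len(x), len(y)))
        ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (max(len(x), len(y)) <= 25 and not ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return TestResult(float(res.statistic), float(res.pvalue),
                          "wilcoxon", (len(x), len(y)))
    if kind == "chi2_yates":
        table = np.asarray(data[0], float)
        if table.shape != (2, 2):
            raise ValueError("chi2_yates needs a 2x2 table")
        if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
            raise ValueError(f"zero margin in 2x2 table {table.tolist()}")
        chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
        return TestResult(float(chi2), float(p), "chi2_yates",
                          tuple(int(v) for v in table.sum(1)))
    if kind == "two_proportion_z":
        k1, n1, k2, n2 = data
        if min(n1, n2) == 0:
            raise ValueError("two_proportion_z needs non-empty groups")
        p1, p2, pbar = k1 / n1, k2 / n2, (k1 + k2) / (n1 + n2)
        se = np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
        z = 0.0 if se == 0 else (p1 - p2) / se
        return TestResult(float(z), float(2 * stats.norm.sf(abs(z))),
                          "two_proportion_z", (int(n1), int(n2)))
    if kind in ("pearson", "spearman"):
        x, y = np.asarray(data[0], float), np.asarray(data[1], float)
        if len(x) < 3:
            raise ValueError("correlation needs n >= 3")
        fn = stats.pearsonr if kind == "pearson" else stats.spearmanr
        res = fn(x, y)
        return TestResult(float(res.statistic), float(res.pvalue), kind, (len(x),))
    raise ValueError(f"unknown test kind {kind!r}")


def adjust_pvalues(results: list[TestResult], method: str = "bonferroni") -> list[TestResult]:
    """Attach family-wise adjusted p-values (Bonferroni or Benjamini-Hochberg)."""
    if not results:
        return results
    pvals = [r.p_value for r in results]
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[method]
    adj = multipletests(pvals, method=key)[1]
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
    return results


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH-adjusted p-values for a raw p-vector."""
    return multipletests(np.asarray(pvals, float), method="fdr_bh")[1]
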