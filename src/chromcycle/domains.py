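"""Broad-domain segmentation and domain-centred analyses.

Domains are merged broad peaks (the multi-kilobase, multi-gene pattern of a
gene-body silencing mark).  Border proximity to TSS/TES points is tested
against uniformly drawn random anchor positions; genes are classified by
joint domain / repeat-mark status and compared across groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_features import TestResult, stat_test, adjust_pvalues
from .io_formats import GenomeAnnotation, Interval
from .signal_peaks import Peak, PeakSet


@dataclass(frozen=True)
class Domain:
    interval: Interval
    score: float      # length-weighted mean of merged peak scores

    def __len__(self) -> int:
        return len(self.interval)


@dataclass
class DomainSet:
    mark: str
    generation: str
    domains: list[Domain] = field(default_factory=list)

    def __post_init__(self):
        self.domains = sorted(self.domains,
                              key=lambda d: (d.interval.scaffold, d.interval.start))

    def __len__(self) -> int:
        return len(self.domains)

    def longer_than(self, min_len: int) -> list[Domain]:
        return [d for d in self.domains if len(d) >= min_len]

    @property
    def total_bp(self) -> int:
        return sum(len(d) for d in self.domains)


@dataclass
class BorderDistanceResult:
    observed: np.ndarray
    null: np.ndarray
    fraction_within_1kb: float
    test: TestResult


@dataclass(frozen=True)
class DomainGeneClass:
    gene_id: str
    in_domain: bool
    has_repeat_mark_peak: bool

    @property
    def joint(self) -> str:
        if self.in_domain and self.has_repeat_mark_peak:
            return "both"
        if self.in_domain:
            return "domain_only"
        if self.has_repeat_mark_peak:
            return "repeat_mark_only"
        return "neither"


# ---------------------------------------------------------------------------

def segment_domains(broad_peaks: PeakSet, merge_gap: int = 1000) -> DomainSet:
    """Merge broad peaks separated by at most ``merge_gap`` bp."""
    domains: list[Domain] = []
    current: list[Peak] = []
    for p in broad_peaks.peaks:
        if (current and p.interval.scaffold == current[-1].interval.scaffold
                and p.interval.start - current[-1].interval.end <= merge_gap):
            current.append(p)
        else:
            if current:
                domains.append(_merge_run(current))
            current = [p]
    if current:
        domains.append(_merge_run(current))
    return DomainSet(broad_peaks.mark, broad_peaks.generation, domains)


def _merge_run(run: list[Peak]) -> Domain:
    iv = Interval(run[0].interval.scaffold, run[0].interval.start,
                  run[-1].interval.end)
    w = np.array([len(p.interval) for p in run], float)
    s = np.array([p.score for p in run], float)
    return Domain(iv, float((w * s).sum() / w.sum()))


def domain_summary(domains: DomainSet, annotation: GenomeAnnotation,
                   long_len: int = 5000, gene_threshold: float = 0.5) -> dict:
    """Total coverage, genome fraction, fraction of domains longer than
    ``long_len`` and mean genes per long domain (a gene counts when more
    than ``gene_threshold`` of its body lies inside)."""
    total = domains.total_bp
    long_domains = domains.longer_than(long_len)
    out = {
        "n_domains": len(domains),
        "total_bp": total,
        "genome_fraction": total / annotation.genome_length,
        "fraction_longer": len(long_domains) / len(domains) if len(domains) else 0.0,
        "mean_genes_per_long_domain": None,
    }
    if long_domains:
        counts = []
        for d in long_domains:
            n = 0
            for g in annotation.genes_on(d.interval.scaffold):
                if d.interval.overlap(g.interval) > gene_threshold * g.length:
                    n += 1
            counts.append(n)
        out["mean_genes_per_long_domain"] = float(np.mean(counts))
    return out


# ---------------------------------------------------------------------------
# border proximity
# ---------------------------------------------------------------------------

def _point_arrays(annotation: GenomeAnnotation) -> dict[str, np.ndarray]:
    pts: dict[str, list[int]] = {s: [] for s in annotation.scaffolds}
    for g in annotation.genes:
        pts[g.scaffold].extend((g.tss, g.tes))
    return {s: np.array(sorted(v), dtype=float) for s, v in pts.items() if v}


def _nearest_distance(points: np.ndarray, x: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(points, x)
    left = np.abs(x - points[np.clip(idx - 1, 0, len(points) - 1)])
    right = np.abs(points[np.clip(idx, 0, len(points) - 1)] - x)
    return np.minimum(left, right)


def border_proximity_test(domains: DomainSet, annotation: GenomeAnnotation,
                          min_len: int = 5000, n_anchor_draws: int = 1000,
                          rng: np.random.Generator | None = None) -> BorderDistanceResult:
    """Distances from long-domain borders to the nearest TSS-or-TES point,
    against a null of uniformly placed anchors (same count per draw), with a
    two-sided Wilcoxon rank-sum test of observed vs pooled null distances."""
    rng = rng if rng is not None else np.random.default_rng()
    qualifying = domains.longer_than(min_len)
    if not qualifying:
        raise ValueError(f"no domains of at least {min_len} bp (0 qualifying)")
    points = _point_arrays(annotation)
    if not points:
        raise ValueError("annotation has no genes")

    observed = []
    for d in qualifying:
        pts = points.get(d.interval.scaffold)
        if pts is None:
            continue
        observed.extend(_nearest_distance(
            pts, np.array([d.interval.start, d.interval.end], float)))
    observed = np.array(observed)

    names = [s for s in annotation.scaffolds if s in points]
    lengths = np.array([annotation.scaffolds[s] for s in names], float)
    cuml = np.concatenate([[0.0], np.cumsum(lengths)])
    n_borders = len(observed)
    null = np.empty((n_anchor_draws, n_borders))
    for k in range(n_anchor_draws):
        flat = rng.uniform(0, cuml[-1], n_borders)
        scaf_idx = np.searchsorted(cuml, flat, side="right") - 1
        local = flat - cuml[scaf_idx]
        for i, (si, x) in enumerate(zip(scaf_idx, local)):
            null[k, i] = _nearest_distance(points[names[si]], np.array([x]))[0]
    null = null.ravel()

    test = stat_test("wilcoxon", observed, null)
    return BorderDistanceResult(
        observed, null, float((observed <= 1000).mean()), test)


def generation_overlap(domains_sp: DomainSet, domains_ga: DomainSet,
                       min_len: int = 5000, reciprocal: float | None = None) -> dict:
    """Fractions of long domains unique to each generation.

    Default uniqueness criterion is any-overlap (>= 1 bp with a domain of
    any length on the other side); ``reciprocal`` switches to requiring that
    fraction of mutual overlap instead.
    """
    def unique_fraction(query: DomainSet, other: DomainSet) -> float:
        qualifying = query.longer_than(min_len)
        if not qualifying:
            return 0.0
        n_unique = 0
        for d in qualifying:
            hit = False
            for o in other.domains:
                ov = d.interval.overlap(o.interval)
                if reciprocal is None:
                    if ov > 0:
                        hit = True
                        break
                elif ov >= reciprocal * len(d) and ov >= reciprocal * len(o):
                    hit = True
                    break
            if not hit:
                n_unique += 1
        return n_unique / len(qualifying)

    return {"unique_sp": unique_fraction(domains_sp, domains_ga),
            "unique_ga": unique_fraction(domains_ga, domains_sp)}


# ---------------------------------------------------------------------------
# gene classification and group comparisons
# ---------------------------------------------------------------------------

def classify_genes_by_domain(annotation: GenomeAnnotation, domains: DomainSet,
                             repeat_mark_peaks: PeakSet | None = None,
                             threshold: float = 0.5) -> dict[str, DomainGeneClass]:
    """A gene is in-domain when strictly more than ``threshold`` of its body
    overlaps a domain; it carries the repeat mark when its body overlaps any
    such peak by >= 1 bp."""
    by_scaf_dom: dict[str, list[Domain]] = {}
    for d in domains.domains:
        by_scaf_dom.setdefault(d.interval.scaffold, []).append(d)
    out = {}
    for g in annotation.genes:
        ov = sum(d.interval.overlap(g.interval)
                 for d in by_scaf_dom.get(g.scaffold, []))
        in_dom = ov > threshold * g.length
        has_peak = False
        if repeat_mark_peaks is not None:
            has_peak = any(p.interval.overlap(g.interval) > 0
                           for p in repeat_mark_peaks.on(g.scaffold))
        out[g.id] = DomainGeneClass(g.id, in_dom, has_peak)
    return out


def group_comparison(classes: dict[str, DomainGeneClass], metric: dict[str, float],
                     grouping: str = "in_out") -> dict:
    """Pairwise Bonferroni-adjusted Wilcoxon tests of a per-gene metric over
    domain groups, with the additivity check for the joint grouping (the
    doubly-marked group median below both singly-marked medians)."""
    values = {gid: metric[gid] for gid in classes if gid in metric
              and metric[gid] is not None and not np.isnan(metric[gid])}
    if len(values) <= 0.5 * len(classes):
        raise ValueError("metric absent for more than half of the genes")
    if grouping == "in_out":
        groups = {"in": [], "out": []}
        for gid, v in values.items():
            groups["in" if classes[gid].in_domain else "out"].append(v)
    elif grouping == "joint4":
        groups = {"neither": [], "domain_only": [], "repeat_mark_only": [], "both": []}
        for gid, v in values.items():
            groups[classes[gid].joint].append(v)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    empty = [k for k, v in groups.items() if not v]
    groups = {k: v for k, v in groups.items() if v}
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    medians = {k: float(np.median(v)) for k, v in groups.items()}
    names = list(groups)
    tests, labels = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            tests.append(stat_test("wilcoxon", groups[names[i]], groups[names[j]]))
            labels.append((names[i], names[j]))
    adjust_pvalues(tests, "bonferroni")

    additive = None
    if {"both", "domain_only", "repeat_mark_only"} <= set(medians):
        additive = medians["both"] < min(medians["domain_only"],
                                         medians["repeat_mark_only"])
    return {"medians": medians, "pairs": labels, "tests": tests,
            "additive": additive, "empty_groups": empty,
            "n": {k: len(v) for k, v in groups.items()}}
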