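"""Peak calling and peak-centred summaries.

The caller is a deliberately simple Poisson bin test against an input
control with Benjamini-Hochberg correction across bins — a transparent
stand-in for a full read-level caller.  Everything downstream (TSS
association, feature-class distribution, co-localisation, transposon
association, metagene and decile profiles) consumes its output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genome_features import FeatureClassMap, TestResult, stat_test
from .io_formats import Gene, GenomeAnnotation, Interval, SignalTrack


@dataclass(frozen=True)
class Peak:
    interval: Interval
    score: float          # -log10 of the best adjusted p in the peak
    summit: int           # midpoint of the most enriched bin


@dataclass
class PeakSet:
    mark: str
    generation: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self):
        self.peaks = sorted(self.peaks, key=lambda p: (p.interval.scaffold,
                                                       p.interval.start))

    def __len__(self) -> int:
        return len(self.peaks)

    def on(self, scaffold: str) -> list[Peak]:
        return [p for p in self.peaks if p.interval.scaffold == scaffold]

    @property
    def total_bp(self) -> int:
        return sum(len(p.interval) for p in self.peaks)


@dataclass
class MetaProfileMatrix:
    """Per-gene signal over 5' flank (native bins), scaled gene body and
    3' flank, strand-flipped so 5' is always on the left."""

    genes: list[str]
    values: np.ndarray          # genes x columns, NaN outside scaffold bounds
    n_flank_bins: int
    n_body_bins: int

    @property
    def profile(self) -> np.ndarray:
        return np.nanmean(self.values, axis=0)

    @property
    def tss_column(self) -> int:
        """First gene-body column (the TSS boundary)."""
        return self.n_flank_bins


# ---------------------------------------------------------------------------
# peak calling
# ---------------------------------------------------------------------------

def average_tracks(tracks: list[SignalTrack]) -> SignalTrack:
    """Mean of library-normalized replicate tracks (values on a CPM scale)."""
    first = tracks[0]
    for t in tracks[1:]:
        if t.bin_size != first.bin_size or t.scaffolds != first.scaffolds:
            raise ValueError("replicate tracks on different bin grids")
    values = {
        name: np.mean([t.normalized(name) for t in tracks], axis=0)
        for name in first.scaffolds
    }
    return SignalTrack(first.bin_size, dict(first.scaffolds), values,
                       first.mark, first.generation, 0)


def call_peaks(track: SignalTrack, control: SignalTrack | None, mode: str = "narrow",
               q_threshold: float = 0.01, min_len: int | None = None,
               max_gap: int | None = None, local_window: int = 10_000) -> PeakSet:
    """Poisson-tail peak caller with BH correction across all bins.

    Per bin the null rate is ``max(global control mean, local control mean
    in a 10 kb window)`` scaled for library size.  Adjacent significant bins
    are merged when separated by at most ``max_gap`` (narrow: one bin;
    broad: 1 kb) and peaks shorter than ``min_len`` are dropped.
    """
    if mode not in ("narrow", "broad"):
        raise ValueError(f"unknown mode {mode!r}")
    if control is not None and (control.bin_size != track.bin_size
                                or control.scaffolds != track.scaffolds):
        raise ValueError("track and control on different bin grids")
    if max_gap is None:
        max_gap = track.bin_size if mode == "narrow" else 1000
    if min_len is None:
        min_len = 2 * track.bin_size if mode == "narrow" else 4 * track.bin_size

    lib = track.library_size
    if lib == 0:
        return PeakSet(track.mark, track.generation, [])
    ctrl = control if control is not None else track
    scale = lib / ctrl.library_size if ctrl.library_size > 0 else 0.0
    w = max(1, local_window // track.bin_size)
    kernel = np.ones(w) / w

    lam, counts = {}, {}
    for name in track.scaffolds:
        c = ctrl.values[name]
        local = np.convolve(c, kernel, mode="same")
        lam[name] = np.maximum(c.mean(), local) * scale
        counts[name] = track.values[name]

    all_p = np.concatenate([
        stats.poisson.sf(np.round(counts[n]) - 1, np.maximum(lam[n], 1e-9))
        for n in track.scaffolds
    ])
    if np.all(all_p >= 1.0):
        return PeakSet(track.mark, track.generation, [])
    from .genome_features import benjamini_hochberg
    all_q = benjamini_hochberg(all_p)

    peaks, offset = [], 0
    for name in track.scaffolds:
        n = len(counts[name])
        q = all_q[offset:offset + n]
        offset += n
        sig = np.where(q <= q_threshold)[0]
        if len(sig) == 0:
            continue
        gap_bins = max_gap // track.bin_size
        runs = []
        run_start = prev = sig[0]
        for i in sig[1:]:
            if i - prev - 1 > gap_bins:
                runs.append((run_start, prev))
                run_start = i
            prev = i
        runs.append((run_start, prev))
        length = track.scaffolds[name]
        for i0, i1 in runs:
            s, e = i0 * track.bin_size, min((i1 + 1) * track.bin_size, length)
            if e - s < min_len:
                continue
            enrich = counts[name][i0:i1 + 1] / np.maximum(lam[name][i0:i1 + 1], 1e-9)
            best = i0 + int(np.argmax(enrich))
            summit = min(best * track.bin_size + track.bin_size // 2, length - 1)
            score = float(-np.log10(max(q[i0:i1 + 1].min(), 1e-300)))
            peaks.append(Peak(Interval(name, s, e), score, summit))
    return PeakSet(track.mark, track.generation, peaks)


# ---------------------------------------------------------------------------
# peak/TSS association and class distribution
# ---------------------------------------------------------------------------

def tss_presence(peaks: PeakSet, genes: list[Gene], window: int = 500) -> dict:
    """Gene marked iff some peak lies within ``window`` bp of its TSS point
    (distance 0 when the TSS is inside a peak)."""
    marked: dict[str, bool] = {}
    by_scaf: dict[str, list[Peak]] = {}
    for p in peaks.peaks:
        by_scaf.setdefault(p.interval.scaffold, []).append(p)
    starts = {s: np.array([p.interval.start for p in ps]) for s, ps in by_scaf.items()}
    ends = {s: np.array([p.interval.end for p in ps]) for s, ps in by_scaf.items()}
    for g in genes:
        if g.scaffold not in starts:
            marked[g.id] = False
            continue
        d = np.maximum.reduce([
            starts[g.scaffold] - g.tss,
            g.tss - ends[g.scaffold],
            np.zeros(len(starts[g.scaffold]), dtype=int),
        ])
        marked[g.id] = bool(d.min() <= window)
    frac = sum(marked.values()) / len(marked) if marked else 0.0
    return {"marked": marked, "fraction": frac}


def gene_body_presence(peaks: PeakSet, genes: list[Gene],
                       min_overlap: float = 0.2) -> dict:
    """Gene carries a body mark iff peaks cover more than ``min_overlap`` of
    its body (the presence rule for gene-body marks; a declared default)."""
    marked = {}
    for g in genes:
        ov = sum(p.interval.overlap(g.interval) for p in peaks.on(g.scaffold))
        marked[g.id] = bool(ov > min_overlap * g.length)
    frac = sum(marked.values()) / len(marked) if marked else 0.0
    return {"marked": marked, "fraction": frac}


def peak_class_distribution(peaks: PeakSet, fmap: FeatureClassMap) -> dict[str, float]:
    """Peak bp distributed over feature classes; proportions sum to 1."""
    totals: dict[str, int] = {}
    for p in peaks.peaks:
        for label, bp in fmap.labels_in(p.interval).items():
            totals[label] = totals.get(label, 0) + bp
    grand = sum(totals.values())
    if grand == 0:
        return {}
    return {label: bp / grand for label, bp in sorted(totals.items())}


# ---------------------------------------------------------------------------
# co-localisation
# ---------------------------------------------------------------------------

def colocalization_matrix(items: dict[str, SignalTrack] | dict[str, PeakSet]) -> dict:
    """Pairwise Pearson r of binned tracks, or Jaccard bp overlap of peak
    sets; symmetric with unit diagonal.  Constant tracks give None."""
    names = list(items)
    if len(names) < 2:
        raise ValueError("need at least two marks")
    k = len(names)
    mat = [[1.0] * k for _ in range(k)]
    first = items[names[0]]
    if isinstance(first, SignalTrack):
        vecs = {
            n: np.concatenate([items[n].normalized(s) for s in items[n].scaffolds])
            for n in names
        }
        for i in range(k):
            for j in range(i + 1, k):
                x, y = vecs[names[i]], vecs[names[j]]
                if np.all(x == x[0]) or np.all(y == y[0]):
                    r = None
                else:
                    r = float(stats.pearsonr(x, y).statistic)
                mat[i][j] = mat[j][i] = r
    else:
        masks = {}
        for n in names:
            bp = {}
            for p in items[n].peaks:
                bp.setdefault(p.interval.scaffold, []).append(p.interval)
            masks[n] = bp
        for i in range(k):
            for j in range(i + 1, k):
                inter, union = _jaccard_bp(masks[names[i]], masks[names[j]])
                mat[i][j] = mat[j][i] = (inter / union) if union else None
    return {"marks": names, "matrix": mat}


def _jaccard_bp(a: dict[str, list[Interval]], b: dict[str, list[Interval]]):
    inter = union = 0
    for scaf in set(a) | set(b):
        ia = _merge(a.get(scaf, []))
        ib = _merge(b.get(scaf, []))
        la = sum(e - s for s, e in ia)
        lb = sum(e - s for s, e in ib)
        ov = 0
        for s1, e1 in ia:
            for s2, e2 in ib:
                ov += max(0, min(e1, e2) - max(s1, s2))
        inter += ov
        union += la + lb - ov
    return inter, union


def _merge(ivs: list[Interval]) -> list[tuple[int, int]]:
    spans = sorted((iv.start, iv.end) for iv in ivs)
    out: list[list[int]] = []
    for s, e in spans:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


# ---------------------------------------------------------------------------
# transposon association
# ---------------------------------------------------------------------------

def te_association_test(peaks: PeakSet, regions_with_te: list[Interval],
                        regions_without_te: list[Interval]) -> TestResult:
    """chi-square (Yates) of peak occupancy against TE content over two
    disjoint region sets; also reports the fraction of peaks overlapping a
    TE-containing region."""
    if not regions_with_te or not regions_without_te:
        raise ValueError("both region sets must be non-empty")

    def occupied(regions):
        hit = 0
        for r in regions:
            for p in peaks.on(r.scaffold):
                if p.interval.overlap(r) > 0:
                    hit += 1
                    break
        return hit

    k_te = occupied(regions_with_te)
    k_no = occupied(regions_without_te)
    table = [[k_te, len(regions_with_te) - k_te],
             [k_no, len(regions_without_te) - k_no]]
    res = stat_test("chi2_yates", table)
    n_peaks = len(peaks)
    coloc = 0
    for p in peaks.peaks:
        if any(p.interval.overlap(r) > 0 for r in regions_with_te):
            coloc += 1
    res.extra["coloc_fraction"] = coloc / n_peaks if n_peaks else float("nan")
    res.extra["table"] = table
    return res


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------

def metaprofile(track: SignalTrack, genes: list[Gene], flank_bp: int = 2000,
                n_body_bins: int = 100) -> MetaProfileMatrix:
    """Fixed-bp flanks at native bins plus a gene body resampled to
    ``n_body_bins`` by length-weighted interpolation."""
    if not genes:
        raise ValueError("metaprofile needs at least one gene")
    bs = track.bin_size
    nf = flank_bp // bs
    ncol = 2 * nf + n_body_bins
    out = np.full((len(genes), ncol), np.nan)
    cum = {}
    for name in track.scaffolds:
        vals = track.normalized(name)
        widths = track.bin_widths(name)
        cum[name] = (np.concatenate([[0.0], np.cumsum(vals * widths)]),
                     np.concatenate([[0.0], np.cumsum(widths)]))
    for gi, g in enumerate(genes):
        arr = track.normalized(g.scaffold)
        length = track.scaffolds[g.scaffold]
        row = np.full(ncol, np.nan)
        # upstream flank at native bins, 5' -> gene
        up = []
        for i in range(nf):
            pos = g.interval.start - flank_bp + i * bs + bs // 2
            up.append(arr[pos // bs] if 0 <= pos < length else np.nan)
        down = []
        for i in range(nf):
            pos = g.interval.end + i * bs + bs // 2
            down.append(arr[pos // bs] if 0 <= pos < length else np.nan)
        csum, cpos = cum[g.scaffold]
        edges = np.linspace(g.interval.start, g.interval.end, n_body_bins + 1)
        ints = np.interp(edges, cpos, csum)
        body = np.diff(ints) / np.diff(edges)
        if g.strand == "+":
            row[:nf] = up
            row[nf:nf + n_body_bins] = body
            row[nf + n_body_bins:] = down
        else:
            row[:nf] = down[::-1]
            row[nf:nf + n_body_bins] = body[::-1]
            row[nf + n_body_bins:] = up[::-1]
        out[gi] = row
    return MetaProfileMatrix([g.id for g in genes], out, nf, n_body_bins)


def decile_profiles(track: SignalTrack, genes: list[Gene], tpm,
                    flank_bp: int = 2000, n_body_bins: int = 100) -> list[np.ndarray]:
    """Mean metagene profile per TPM decile (deciles 1..10, low to high)."""
    if len(genes) < 10:
        raise ValueError("decile profiles need at least 10 genes")
    order = sorted(genes, key=lambda g: (float(tpm[g.id]), g.id))
    groups = np.array_split(np.arange(len(order)), 10)
    profiles = []
    for idx in groups:
        mp = metaprofile(track, [order[i] for i in idx], flank_bp, n_body_bins)
        profiles.append(mp.profile)
    return profiles


def tss_window_signal(track: SignalTrack, genes: list[Gene], window: int = 500):
    """Mean normalized signal in TSS +/- window per gene (pandas-free dict)."""
    return {
        g.id: track.mean_in(g.scaffold, g.tss - window, g.tss + window)
        for g in genes
    }
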