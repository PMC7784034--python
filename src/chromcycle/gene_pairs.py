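"""Divergent vs tandem gene-pair analyses.

Closely spaced divergent promoters share a chromatin domain: the analyses
here quantify TSS signal by pair orientation and intergenic length, call
nucleosome-depleted regions (NDRs) from MNase coverage and ask whether one
NDR spans both TSSs, correlate expression within pairs, and summarise
co-regulation of adjacent lncRNA / coding generation-biased genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chromatin_states import GBGTable
from .genome_features import GenePair, TestResult, stat_test
from .io_formats import ExpressionTable, GenomeAnnotation, Interval, SignalTrack


@dataclass(frozen=True)
class NDRCall:
    interval: Interval
    depth: float                 # fractional dip below local background
    spans_both_tss: bool = False


# ---------------------------------------------------------------------------
# TSS signal by orientation
# ---------------------------------------------------------------------------

def pair_tss_signal(tracks: dict[str, SignalTrack], pairs: list[GenePair],
                    window: int = 500,
                    length_bins=(0, 600, 1000, 2000, 5000, np.inf)) -> dict:
    """Mean signal in gene-2's TSS window per mark, with divergent-vs-tandem
    Wilcoxon tests and a length-stratified median summary.

    Gene 2 is the right-hand gene of the pair in scaffold coordinates.
    """
    if not pairs:
        raise ValueError("pair set is empty")
    rows = []
    for p in pairs:
        rec = {"left": p.left.id, "right": p.right.id,
               "orientation": p.orientation, "length": p.length}
        g2 = p.right
        for mark, tr in tracks.items():
            rec[mark] = tr.mean_in(g2.scaffold, g2.tss - window, g2.tss + window)
        rows.append(rec)
    table = pd.DataFrame(rows)

    tests: dict[str, TestResult] = {}
    div = table[table.orientation == "divergent"]
    tan = table[table.orientation == "tandem"]
    for mark in tracks:
        if len(div) and len(tan):
            tests[mark] = stat_test("wilcoxon", div[mark].to_numpy(),
                                    tan[mark].to_numpy())

    strata = []
    for lo, hi in zip(length_bins, length_bins[1:]):
        sel = (table.length >= lo) & (table.length < hi)
        for orient in ("divergent", "tandem"):
            sub = table[sel & (table.orientation == orient)]
            if len(sub):
                strata.append({
                    "stratum": f"[{lo:g}, {hi:g})", "orientation": orient,
                    "n": len(sub),
                    **{m: float(sub[m].median()) for m in tracks},
                })
    return {"records": table, "tests": tests,
            "length_strata": pd.DataFrame(strata)}


# ---------------------------------------------------------------------------
# NDR detection from MNase coverage
# ---------------------------------------------------------------------------

def detect_ndr(mnase: SignalTrack, region: Interval,
               background_window: int = 5000, depth_threshold: float = 0.5,
               min_width: int | None = None,
               tss_points: tuple[int, int] | None = None) -> list[NDRCall]:
    """NDRs inside ``region``: maximal runs of bins below ``depth_threshold``
    times the local background (median MNase signal over a window centred on
    the region).  Scale-invariant by construction.
    """
    bs = mnase.bin_size
    if len(region) < bs:
        raise ValueError("region shorter than one bin")
    if min_width is None:
        min_width = bs
    length = mnase.scaffolds[region.scaffold]
    arr = mnase.normalized(region.scaffold)
    mid = (region.start + region.end) // 2
    b0 = max(0, (mid - background_window // 2) // bs)
    b1 = min(len(arr), (mid + background_window // 2) // bs + 1)
    background = float(np.median(arr[b0:b1]))
    if background <= 0:
        return []
    i0, i1 = region.start // bs, min((region.end - 1) // bs + 1, len(arr))
    below = arr[i0:i1] < depth_threshold * background

    calls: list[NDRCall] = []
    run_start = None
    for i, flag in enumerate(np.append(below, False)):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            s = (i0 + run_start) * bs
            e = min((i0 + i) * bs, length)
            if e - s >= min_width:
                depth = 1.0 - float(arr[i0 + run_start:i0 + i].mean()) / background
                spans = False
                if tss_points is not None:
                    spans = all(s - bs <= t <= e + bs for t in tss_points)
                calls.append(NDRCall(Interval(region.scaffold, s, e),
                                     max(min(depth, 1.0), 0.0), spans))
            run_start = None
    return calls


def shared_ndr_rate(pairs: list[GenePair], mnase: SignalTrack,
                    length_threshold: int = 600, flank: int = 200,
                    depth_threshold: float = 0.5) -> dict:
    """Fraction of divergent pairs whose two TSSs sit inside one NDR,
    reported for gaps <= ``length_threshold`` and above it."""
    divergent = [p for p in pairs
                 if p.orientation == "divergent" and not p.overlapping]
    if not divergent:
        raise ValueError("no divergent pairs")
    shared = {"le": [], "gt": []}
    for p in divergent:
        t1, t2 = p.left.tss, p.right.tss
        length = mnase.scaffolds[p.left.scaffold]
        region = Interval(p.left.scaffold,
                          max(0, min(t1, t2) - flank),
                          min(length, max(t1, t2) + flank))
        calls = detect_ndr(mnase, region, depth_threshold=depth_threshold,
                           tss_points=(t1, t2))
        hit = any(c.spans_both_tss for c in calls)
        shared["le" if p.length <= length_threshold else "gt"].append(hit)
    return {
        "rate_le": float(np.mean(shared["le"])) if shared["le"] else None,
        "rate_gt": float(np.mean(shared["gt"])) if shared["gt"] else None,
        "n_le": len(shared["le"]), "n_gt": len(shared["gt"]),
    }


# ---------------------------------------------------------------------------
# expression within pairs
# ---------------------------------------------------------------------------

def pair_expression_correlation(expr: ExpressionTable, pairs: list[GenePair],
                                subset: str = "divergent",
                                max_length: float | None = None) -> TestResult:
    """Pearson r of log2(TPM + 1) between the two members of each pair."""
    mean_tpm = expr.tpm.mean(axis=1)
    chosen = []
    for p in pairs:
        if subset != "all" and p.orientation != "divergent":
            continue
        if max_length is not None and p.length >= max_length:
            continue
        if p.left.id in mean_tpm.index and p.right.id in mean_tpm.index:
            chosen.append((mean_tpm[p.left.id], mean_tpm[p.right.id]))
    if len(chosen) < 3:
        raise ValueError(f"only {len(chosen)} pairs in subset; need >= 3")
    x = np.log2(np.array([c[0] for c in chosen]) + 1)
    y = np.log2(np.array([c[1] for c in chosen]) + 1)
    return stat_test("pearson", x, y)


def adjacent_gbg_coregulation(gbgs: GBGTable, pairs: list[GenePair]) -> dict:
    """lncRNA GBGs whose adjacent partner is a protein-coding GBG, and the
    fraction upregulated in the same generation."""
    bias = gbgs.table["bias"]
    seen: set[str] = set()
    co = []
    for p in pairs:
        for lnc, cod in ((p.left, p.right), (p.right, p.left)):
            if (lnc.biotype == "lncRNA" and cod.biotype == "protein_coding"
                    and lnc.id in bias.index and cod.id in bias.index
                    and lnc.id not in seen):
                seen.add(lnc.id)
                co.append(bias[lnc.id] == bias[cod.id])
    return {
        "n_adjacent": len(co),
        "fraction_codirectional": float(np.mean(co)) if co else None,
    }
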