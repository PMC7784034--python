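"""Combinatorial chromatin states and generation-biased expression.

Sixteen states are the presence/absence combinations of four TSS-localised
marks (H3K4me2, H3K4me3, H3K9ac, H3K27ac).  State ids order the subsets by
descending mark count, ties broken by the canonical mark order, so state 1
is all four present and state 16 none — the id map is declared here, not a
claim about any external numbering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .genome_features import TestResult, benjamini_hochberg, stat_test
from .io_formats import ExpressionTable, GenomeAnnotation

STATE_MARKS = ("H3K4me2", "H3K4me3", "H3K9ac", "H3K27ac")

# declared bijection subset <-> id
_SUBSETS = sorted(
    (frozenset(c) for r in range(5) for c in combinations(STATE_MARKS, r)),
    key=lambda s: (-len(s), tuple(STATE_MARKS.index(m) for m in sorted(
        s, key=STATE_MARKS.index))),
)
STATE_OF_SUBSET = {s: i + 1 for i, s in enumerate(_SUBSETS)}
SUBSET_OF_STATE = {i + 1: s for i, s in enumerate(_SUBSETS)}


@dataclass
class GBGTable:
    """Generation-biased genes: bias direction, fold change, biotype."""

    table: pd.DataFrame           # index gene_id: bias, log2fc, biotype
    conflicting: int = 0          # direction conflicts across experiments

    def __len__(self) -> int:
        return len(self.table)

    def of_bias(self, bias: str) -> list[str]:
        return list(self.table.index[self.table["bias"] == bias])


@dataclass
class TransitionSummary:
    counts: pd.DataFrame                    # 16x16, sp state x ga state
    fraction_unchanged: float
    fraction_unchanged_state1: float | None
    fraction_gain_concordant: float | None
    to_state1: dict[str, float]             # per bias, among state-changers
    z_test: TestResult | None
    state1_fc_test: TestResult | None
    n_changers: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def compute_tpm(counts: pd.DataFrame, effective_lengths: pd.Series) -> pd.DataFrame:
    """TPM_i = 1e6 * (c_i / L_i) / sum_j (c_j / L_j), per sample."""
    if (effective_lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    if (counts < 0).to_numpy().any():
        raise ValueError("counts must be non-negative")
    rate = counts.div(effective_lengths.loc[counts.index], axis=0)
    denom = rate.sum(axis=0)
    if (denom == 0).any():
        bad = denom.index[denom == 0][0]
        raise ValueError(f"all-zero sample {bad}")
    return rate.div(denom, axis=1) * 1e6


def simple_de_test(expr: ExpressionTable, pseudocount: float = 0.5) -> pd.DataFrame:
    """Built-in differential-expression stand-in.

    log2fc = log2((mean SP TPM + c) / (mean GA TPM + c)); p from a two-sided
    Welch test on log2(TPM + 1) across replicates; padj by BH over genes.
    An externally supplied DE table is a first-class alternative.
    """
    sp_cols = expr.samples_of("sp")
    ga_cols = expr.samples_of("ga")
    if len(sp_cols) < 2 or len(ga_cols) < 2:
        raise ValueError("differential expression needs >= 2 replicates per generation")
    sp = expr.tpm[sp_cols].to_numpy(float)
    ga = expr.tpm[ga_cols].to_numpy(float)
    log2fc = np.log2((sp.mean(1) + pseudocount) / (ga.mean(1) + pseudocount))
    lsp, lga = np.log2(sp + 1), np.log2(ga + 1)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance groups
        _, p = stats.ttest_ind(lsp, lga, axis=1, equal_var=False)
    # identical (zero-variance) groups: no evidence either way -> p = 1
    same = np.isnan(p) & np.isclose(lsp.mean(1), lga.mean(1))
    p = np.where(same, 1.0, p)
    p = np.where(np.isnan(p), 0.0, p)  # zero variance, different means
    return pd.DataFrame(
        {"log2fc": log2fc, "pvalue": p, "padj": benjamini_hochberg(p)},
        index=expr.tpm.index,
    )


def call_gbgs(de_tables: list[pd.DataFrame], expr: ExpressionTable,
              annotation: GenomeAnnotation | None = None,
              padj_threshold: float = 0.05, fold_threshold: float = 2.0,
              tpm_threshold: float = 1.0) -> GBGTable:
    """A gene is generation-biased iff it passes padj, fold and TPM
    thresholds with the same bias direction in every experiment."""
    if not de_tables:
        raise ValueError("need at least one DE table")
    log2_threshold = np.log2(fold_threshold)
    mean_sp = expr.mean_tpm("sp")
    mean_ga = expr.mean_tpm("ga")
    genes = de_tables[0].index
    passing: dict[str, list[str]] = {}
    conflicting = 0
    for gid in genes:
        verdicts = []
        for de in de_tables:
            if gid not in de.index:
                verdicts.append(None)
                continue
            row = de.loc[gid]
            if row["padj"] >= padj_threshold or abs(row["log2fc"]) <= log2_threshold:
                verdicts.append(None)
                continue
            bias = "sp" if row["log2fc"] > 0 else "ga"
            biased_tpm = mean_sp[gid] if bias == "sp" else mean_ga[gid]
            verdicts.append(bias if biased_tpm > tpm_threshold else None)
        if all(v is not None for v in verdicts):
            if len(set(verdicts)) == 1:
                passing.setdefault(verdicts[0], []).append(gid)
            else:
                conflicting += 1
    rows = []
    for bias, ids in passing.items():
        for gid in ids:
            log2fc = float(np.mean([de.loc[gid, "log2fc"] for de in de_tables
                                    if gid in de.index]))
            biotype = annotation.gene(gid).biotype if annotation else None
            rows.append((gid, bias, log2fc, biotype))
    table = pd.DataFrame(rows, columns=["gene_id", "bias", "log2fc", "biotype"])
    table = table.set_index("gene_id").sort_index()
    return GBGTable(table, conflicting)


# ---------------------------------------------------------------------------
# states
# ---------------------------------------------------------------------------

def call_states(presence: pd.DataFrame) -> pd.Series:
    """Map per-gene boolean presence of the four state marks to state ids.

    ``presence`` columns must include the four state marks; the result is a
    Series of ids 1..16 indexed like ``presence``.
    """
    missing = [m for m in STATE_MARKS if m not in presence.columns]
    if missing:
        raise ValueError(f"missing mark columns: {missing}")
    ids = [
        STATE_OF_SUBSET[frozenset(m for m in STATE_MARKS if row[m])]
        for _, row in presence[list(STATE_MARKS)].astype(bool).iterrows()
    ]
    return pd.Series(ids, index=presence.index, name="state")


def stability_summary(presence_sp: pd.DataFrame,
                      presence_ga: pd.DataFrame) -> dict[str, float]:
    """Per mark, the fraction of genes with identical presence in the two
    generations (stably present or stably absent)."""
    common = presence_sp.index.intersection(presence_ga.index)
    out = {}
    for mark in presence_sp.columns:
        if mark in presence_ga.columns:
            out[mark] = float(
                (presence_sp.loc[common, mark].astype(bool)
                 == presence_ga.loc[common, mark].astype(bool)).mean())
    return out


def transition_analysis(states_sp: pd.Series, states_ga: pd.Series,
                        gbgs: GBGTable, de: pd.DataFrame,
                        concordance: str = "net_gain") -> TransitionSummary:
    """Chromatin-state transitions between generations at generation-biased
    genes.

    Reports the 16x16 transition counts, the fraction of GBGs that keep
    their state (and how many of those sit in state 1), gain-concordance
    (state-changers whose biased generation shows a net gain of marks, or a
    strict superset when ``concordance='superset'``), the per-bias fraction
    of transitions landing in state 1 with a two-proportion z test, and a
    Wilcoxon comparison of |log2fc| for state-1 destinations vs others.
    """
    gids = [g for g in gbgs.table.index
            if g in states_sp.index and g in states_ga.index]
    if not gids:
        raise ValueError("GBG set empty or disjoint from the state tables")
    counts = pd.DataFrame(0, index=range(1, 17), columns=range(1, 17))
    for g in gids:
        counts.loc[int(states_sp[g]), int(states_ga[g])] += 1

    unchanged = [g for g in gids if states_sp[g] == states_ga[g]]
    changers = [g for g in gids if states_sp[g] != states_ga[g]]
    frac_unchanged = len(unchanged) / len(gids)
    frac_unchanged_state1 = (
        float(np.mean([states_sp[g] == 1 for g in unchanged])) if unchanged else None
    )

    bias = gbgs.table["bias"]

    def biased_state(g):
        return states_sp[g] if bias[g] == "sp" else states_ga[g]

    def other_state(g):
        return states_ga[g] if bias[g] == "sp" else states_sp[g]

    concordant = None
    if changers:
        flags = []
        for g in changers:
            up = SUBSET_OF_STATE[int(biased_state(g))]
            down = SUBSET_OF_STATE[int(other_state(g))]
            if concordance == "superset":
                flags.append(up > down)
            else:
                flags.append(len(up - down) - len(down - up) > 0)
        concordant = float(np.mean(flags))

    to_state1, n_changers = {}, {}
    for b in ("sp", "ga"):
        ch = [g for g in changers if bias[g] == b]
        n_changers[b] = len(ch)
        to_state1[b] = (float(np.mean([biased_state(g) == 1 for g in ch]))
                        if ch else float("nan"))

    z_test = fc_test = None
    if changers and n_changers["sp"] and n_changers["ga"]:
        k_sp = sum(biased_state(g) == 1 for g in changers if bias[g] == "sp")
        k_ga = sum(biased_state(g) == 1 for g in changers if bias[g] == "ga")
        z_test = stat_test("two_proportion_z", k_sp, n_changers["sp"],
                           k_ga, n_changers["ga"])
        fc = de["log2fc"].abs()
        dest1 = [fc[g] for g in changers if biased_state(g) == 1]
        other = [fc[g] for g in changers if biased_state(g) != 1]
        if dest1 and other:
            fc_test = stat_test("wilcoxon", dest1, other)

    return TransitionSummary(counts, frac_unchanged, frac_unchanged_state1,
                             concordant, to_state1, z_test, fc_test, n_changers)


def lncrna_enrichment(gbgs: GBGTable, annotation: GenomeAnnotation) -> TestResult:
    """2x2 chi-square (Yates) of biotype (lncRNA vs coding) against GBG
    membership over the annotated gene universe."""
    gbg_ids = set(gbgs.table.index)
    lnc_gbg = lnc_other = cod_gbg = cod_other = 0
    for g in annotation.genes:
        is_lnc = g.biotype == "lncRNA"
        is_gbg = g.id in gbg_ids
        if is_lnc and is_gbg:
            lnc_gbg += 1
        elif is_lnc:
            lnc_other += 1
        elif is_gbg:
            cod_gbg += 1
        else:
            cod_other += 1
    res = stat_test("chi2_yates", [[lnc_gbg, lnc_other], [cod_gbg, cod_other]])
    res.extra["lncrna_gbgs"] = lnc_gbg
    return res
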