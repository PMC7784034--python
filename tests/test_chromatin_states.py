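"""TPM, differential expression, GBG calling, states and transitions."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import chromcycle as cc
from chromcycle.chromatin_states import STATE_MARKS, SUBSET_OF_STATE
from util import mk_ann, mk_gene


class TestComputeTpm:
    def test_single_gene_is_million(self):
        counts = pd.DataFrame({"s1": [7]}, index=["g1"])
        tpm = cc.compute_tpm(counts, pd.Series({"g1": 500}))
        assert tpm.loc["g1", "s1"] == pytest.approx(1e6)

    def test_two_genes_length_normalised(self):
        counts = pd.DataFrame({"s1": [100, 100]}, index=["a", "b"])
        tpm = cc.compute_tpm(counts, pd.Series({"a": 1000, "b": 2000}))
        # rates 0.1 and 0.05 -> 2/3 and 1/3 of a million
        assert tpm.loc["a", "s1"] == pytest.approx(2e6 / 3)
        assert tpm.loc["b", "s1"] == pytest.approx(1e6 / 3)

    def test_columns_sum_to_million(self, default_dataset):
        rng = np.random.default_rng(0)
        ids = default_dataset.annotation.gene_ids[:200]
        counts = pd.DataFrame(rng.poisson(50, (200, 3)), index=ids,
                              columns=["a", "b", "c"])
        lengths = pd.Series(rng.integers(300, 5000, 200), index=ids)
        tpm = cc.compute_tpm(counts, lengths)
        assert np.allclose(tpm.sum(axis=0), 1e6, atol=1e-3)

    def test_all_zero_sample_fails(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="all-zero"):
            cc.compute_tpm(counts, pd.Series({"a": 100, "b": 100}))


class TestSimpleDeTest:
    def _expr(self, sp, ga):
        ids = [f"g{i}" for i in range(len(sp))]
        tpm = pd.DataFrame({
            "sp_1": [v[0] for v in sp], "sp_2": [v[1] for v in sp],
            "ga_1": [v[0] for v in ga], "ga_2": [v[1] for v in ga],
        }, index=pd.Index(ids, name="gene_id"))
        gens = {c: c.split("_")[0] for c in tpm.columns}
        return cc.ExpressionTable(tpm, gens)

    def test_identical_groups(self):
        expr = self._expr([(10, 10)], [(10, 10)])
        de = cc.simple_de_test(expr)
        assert de.loc["g0", "log2fc"] == 0.0
        assert de.loc["g0", "pvalue"] == 1.0

    def test_planted_fourfold_noiseless(self):
        expr = self._expr([(40, 40)], [(10, 10)])
        de = cc.simple_de_test(expr)
        assert de.loc["g0", "log2fc"] == pytest.approx(np.log2(40.5 / 10.5))

    def test_padj_matches_brute_force_bh(self, default_dataset):
        de = cc.simple_de_test(default_dataset.expression)
        p = de["pvalue"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        bh = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            running = min(running, p[i] * m / (rank + 1))
            bh[i] = running
        assert np.allclose(de["padj"].to_numpy(), bh)

    def test_requires_two_replicates(self):
        tpm = pd.DataFrame({"sp_1": [1.0], "ga_1": [2.0]},
                           index=pd.Index(["g0"], name="gene_id"))
        expr = cc.ExpressionTable(tpm, {"sp_1": "sp", "ga_1": "ga"})
        with pytest.raises(ValueError, match="replicates"):
            cc.simple_de_test(expr)


class TestCallGbgs:
    def _expr(self):
        tpm = pd.DataFrame({
            "sp_1": [40.0, 40, 40, 40], "sp_2": [40.0, 40, 40, 40],
            "ga_1": [5.0, 5, 5, 5], "ga_2": [5.0, 5, 5, 5],
        }, index=pd.Index([f"g{i}" for i in range(4)], name="gene_id"))
        return cc.ExpressionTable(tpm, {c: c.split("_")[0] for c in tpm})

    def _de(self, padj, log2fc=1.6):
        return pd.DataFrame({"log2fc": [log2fc] * 4, "pvalue": [0.001] * 4,
                             "padj": [padj] * 4},
                            index=pd.Index([f"g{i}" for i in range(4)],
                                           name="gene_id"))

    def test_passing_both_experiments(self):
        gbgs = cc.call_gbgs([self._de(0.04), self._de(0.04)], self._expr())
        assert len(gbgs) == 4 and set(gbgs.table["bias"]) == {"sp"}

    def test_failing_one_experiment_excluded(self):
        gbgs = cc.call_gbgs([self._de(0.04), self._de(0.06)], self._expr())
        assert len(gbgs) == 0

    def test_fold_below_two_excluded(self):
        gbgs = cc.call_gbgs([self._de(0.01, log2fc=np.log2(1.9))], self._expr())
        assert len(gbgs) == 0

    def test_direction_conflict_counted(self):
        gbgs = cc.call_gbgs([self._de(0.01, 1.6), self._de(0.01, -1.6)],
                            self._expr())
        assert len(gbgs) == 0 and gbgs.conflicting == 4

    def test_monotone_in_thresholds(self, default_dataset):
        de = cc.simple_de_test(default_dataset.expression)
        expr = default_dataset.expression
        loose = set(cc.call_gbgs([de], expr, padj_threshold=0.1,
                                 fold_threshold=1.5, tpm_threshold=0.5).table.index)
        tight = set(cc.call_gbgs([de], expr, padj_threshold=0.01,
                                 fold_threshold=4.0, tpm_threshold=2.0).table.index)
        assert tight <= loose


class TestStates:
    def _presence(self, rows):
        return pd.DataFrame(rows, columns=list(STATE_MARKS),
                            index=[f"g{i}" for i in range(len(rows))])

    def test_all_four_is_state_one(self):
        states = cc.call_states(self._presence([[1, 1, 1, 1]]))
        assert states.iloc[0] == 1

    def test_none_is_state_sixteen(self):
        states = cc.call_states(self._presence([[0, 0, 0, 0]]))
        assert states.iloc[0] == 16

    def test_bijection_over_all_subsets(self):
        rows = []
        for r in range(5):
            for combo in combinations(range(4), r):
                rows.append([1 if i in combo else 0 for i in range(4)])
        states = cc.call_states(self._presence(rows))
        assert sorted(states) == list(range(1, 17))
        # invert: the declared subset of every id matches the input row
        for (_, row), sid in zip(self._presence(rows).iterrows(), states):
            subset = frozenset(m for m in STATE_MARKS if row[m])
            assert SUBSET_OF_STATE[sid] == subset

    def test_missing_mark_fails(self):
        df = pd.DataFrame({"H3K4me2": [True]})
        with pytest.raises(ValueError, match="missing"):
            cc.call_states(df)


class TestStability:
    def test_identical_tables(self):
        df = pd.DataFrame({"H3K4me2": [True, False]}, index=["a", "b"])
        assert cc.stability_summary(df, df.copy()) == {"H3K4me2": 1.0}

    def test_one_in_ten_flipped(self):
        sp = pd.DataFrame({"m": [True] * 10}, index=[f"g{i}" for i in range(10)])
        ga = sp.copy()
        ga.iloc[0, 0] = False
        assert cc.stability_summary(sp, ga)["m"] == pytest.approx(0.9)

    def test_default_world_stable(self, default_dataset):
        truth = default_dataset.truth
        stab = cc.stability_summary(truth.presence["sp"], truth.presence["ga"])
        assert all(v >= 0.95 for v in stab.values())


class TestTransitions:
    def _gbgs(self, ids, biases, fcs):
        table = pd.DataFrame({"bias": biases, "log2fc": fcs,
                              "biotype": ["protein_coding"] * len(ids)},
                             index=pd.Index(ids, name="gene_id"))
        return cc.GBGTable(table)

    def _de(self, ids, fcs):
        return pd.DataFrame({"log2fc": fcs, "pvalue": 0.001, "padj": 0.01},
                            index=pd.Index(ids, name="gene_id"))

    def test_no_state_changes(self):
        ids = ["a", "b"]
        states = pd.Series([1, 5], index=ids)
        gbgs = self._gbgs(ids, ["sp", "ga"], [2.0, -2.0])
        tr = cc.transition_analysis(states, states.copy(), gbgs,
                                    self._de(ids, [2.0, -2.0]))
        assert tr.fraction_unchanged == 1.0
        assert tr.z_test is None and tr.state1_fc_test is None
        assert tr.counts.to_numpy().sum() == 2

    def test_identical_transition_profiles_z_zero(self):
        ids = ["a", "b", "c", "d"]
        sp = pd.Series([2, 2, 2, 2], index=ids)
        ga = pd.Series([1, 16, 1, 16], index=ids)
        # sp-biased a/b: destinations (sp states) 2,2; ga-biased c/d: 1,16
        gbgs = self._gbgs(ids, ["sp", "sp", "ga", "ga"], [2, 2, -2, -2])
        # make destination-to-state-1 proportions equal: a->1? reframe:
        sp = pd.Series([1, 16, 2, 2], index=ids)
        ga = pd.Series([2, 2, 1, 16], index=ids)
        tr = cc.transition_analysis(sp, ga, gbgs, self._de(ids, [2, 2, -2, -2]))
        assert tr.z_test.statistic == 0.0

    def test_counts_conserved(self, default_dataset):
        ds = default_dataset
        de = cc.simple_de_test(ds.expression)
        gbgs = cc.call_gbgs([de], ds.expression, ds.annotation)
        st = {g: cc.call_states(ds.truth.presence[g]) for g in ("sp", "ga")}
        tr = cc.transition_analysis(st["sp"], st["ga"], gbgs, de)
        assert tr.counts.to_numpy().sum() == len(gbgs)
        assert sum(tr.n_changers.values()) == int(
            round((1 - tr.fraction_unchanged) * len(gbgs)))


class TestLncrnaEnrichment:
    def _ann(self, biotypes):
        return mk_ann({"chr1": 1_000_000}, [
            mk_gene(f"g{i}", "chr1", 1000 * i + 100, 1000 * i + 600,
                    biotype=b) for i, b in enumerate(biotypes)
        ])

    def test_planted_enrichment_detected(self):
        cfg = cc.SyntheticConfig()
        ds = cc.generate_dataset(cfg, seed=2)
        # plant a 3x-weighted lncRNA GBG set via the generator default
        de = cc.simple_de_test(ds.expression)
        gbgs = cc.call_gbgs([de], ds.expression, ds.annotation)
        res = cc.lncrna_enrichment(gbgs, ds.annotation)
        assert res.extra["lncrna_gbgs"] >= 1

    def test_no_lncrna_zero_margin_fails(self):
        ann = self._ann(["protein_coding"] * 10)
        table = pd.DataFrame({"bias": ["sp"], "log2fc": [2.0],
                              "biotype": ["protein_coding"]},
                             index=pd.Index(["g0"], name="gene_id"))
        with pytest.raises(ValueError, match="margin"):
            cc.lncrna_enrichment(cc.GBGTable(table), ann)
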