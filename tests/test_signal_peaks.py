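"""Peak calling, TSS association, co-localisation and metagene profiles."""

import numpy as np
import pytest

import chromcycle as cc
from util import mk_ann, mk_gene


def _track(values, bin_size=50, scaf="chr1", mark="m"):
    arr = np.asarray(values, float)
    return cc.SignalTrack(bin_size, {scaf: len(arr) * bin_size},
                          {scaf: arr.copy()}, mark, "sp", 1)


class TestCallPeaks:
    def test_flat_track_equal_to_control(self):
        tr = _track(np.full(200, 10.0))
        ctrl = _track(np.full(200, 10.0))
        assert len(cc.call_peaks(tr, ctrl)) == 0

    def test_single_bump_recovered(self):
        vals = np.full(400, 10.0)
        vals[200:206] = 100.0  # 300 bp bump, 10x background
        ps = cc.call_peaks(_track(vals), _track(np.full(400, 10.0)))
        assert len(ps) == 1
        peak = ps.peaks[0]
        argmax_bp = 200 * 50 + 25
        assert peak.interval.start <= argmax_bp < peak.interval.end
        assert peak.interval.start <= peak.summit < peak.interval.end

    def test_mismatched_grids_fail(self):
        with pytest.raises(ValueError, match="grid"):
            cc.call_peaks(_track(np.zeros(100)), _track(np.zeros(100), bin_size=25))

    def test_all_zero_is_empty_not_error(self):
        ps = cc.call_peaks(_track(np.zeros(100)), _track(np.zeros(100)))
        assert len(ps) == 0

    def test_null_calibration_over_seeds(self):
        genome = 200_000
        called = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            tr = _track(rng.poisson(20.0, genome // 50).astype(float))
            ctrl = _track(rng.poisson(20.0, genome // 50).astype(float))
            called.append(cc.call_peaks(tr, ctrl).total_bp / genome)
        assert np.mean(called) <= 0.01


class TestTssPresence:
    def _genes(self, tss):
        return [mk_gene("g", "chr1", tss, tss + 1000, "+")]

    def _peaks(self, start, end):
        return cc.PeakSet("m", "sp", [cc.Peak(cc.Interval("chr1", start, end),
                                              1.0, (start + end) // 2)])

    def test_tss_inside_peak(self):
        res = cc.tss_presence(self._peaks(900, 1200), self._genes(1000))
        assert res["marked"]["g"] and res["fraction"] == 1.0

    def test_window_boundary_exclusive_at_501(self):
        # nearest edge 501 bp away -> unmarked; 500 bp -> marked
        assert not cc.tss_presence(self._peaks(1501, 1600),
                                   self._genes(1000))["marked"]["g"]
        assert cc.tss_presence(self._peaks(1500, 1600),
                               self._genes(1000))["marked"]["g"]

    def test_empty_peakset(self):
        res = cc.tss_presence(cc.PeakSet("m", "sp", []), self._genes(1000))
        assert res["fraction"] == 0.0

    def test_monotone_in_window(self, default_dataset):
        ds = default_dataset
        tr = cc.average_tracks(ds.replicate_tracks("H3K9ac", "sp"))
        ps = cc.call_peaks(tr, ds.input_tracks["sp"])
        genes = ds.annotation.genes
        marked_small = cc.tss_presence(ps, genes, window=200)["marked"]
        marked_big = cc.tss_presence(ps, genes, window=800)["marked"]
        assert all(marked_big[g] for g in marked_small if marked_small[g])


class TestClassDistribution:
    def _setup(self):
        gene = mk_gene("g", "chr1", 1000, 3000, "+",
                       exons=[(1000, 1500), (2500, 3000)])
        ann = mk_ann({"chr1": 10_000}, [gene])
        return cc.build_feature_partition(ann)

    def test_peak_inside_first_exon(self):
        fmap = self._setup()
        ps = cc.PeakSet("m", "sp", [cc.Peak(cc.Interval("chr1", 1100, 1300),
                                            1.0, 1200)])
        dist = cc.peak_class_distribution(ps, fmap)
        assert dist == {"first_exon": 1.0}

    def test_half_and_half(self):
        fmap = self._setup()
        # [1400, 1600): 100 bp first_exon + 100 bp first_intron (no TE)
        ps = cc.PeakSet("m", "sp", [cc.Peak(cc.Interval("chr1", 1400, 1600),
                                            1.0, 1500)])
        dist = cc.peak_class_distribution(ps, fmap)
        assert dist == {"first_exon": 0.5, "first_intron_no_te": 0.5}

    def test_proportions_sum_to_one(self, default_dataset):
        ds = default_dataset
        fmap = cc.build_feature_partition(ds.annotation)
        tr = cc.average_tracks(ds.replicate_tracks("H4K20me3", "sp"))
        ps = cc.call_peaks(tr, ds.input_tracks["sp"])
        dist = cc.peak_class_distribution(ps, fmap)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)

    def test_te_mark_enriched_in_te_bp(self, default_dataset):
        ds = default_dataset
        fmap = cc.build_feature_partition(ds.annotation)
        tr = cc.average_tracks(ds.replicate_tracks("H4K20me3", "sp"))
        ps = cc.call_peaks(tr, ds.input_tracks["sp"])
        dist = cc.peak_class_distribution(ps, fmap)
        totals = fmap.bp_totals()
        genome = sum(totals.values())
        te_labels = [k for k in totals if k.endswith("_te")]
        peak_te = sum(dist.get(k, 0.0) for k in te_labels)
        genome_te = sum(totals[k] for k in te_labels) / genome
        assert peak_te > genome_te


class TestColocalization:
    def test_track_self_correlation(self):
        rng = np.random.default_rng(0)
        t = _track(rng.poisson(20, 500).astype(float))
        res = cc.colocalization_matrix({"a": t, "b": t})
        assert res["matrix"][0][1] == pytest.approx(1.0)

    def test_independent_backgrounds_uncorrelated(self):
        rng = np.random.default_rng(1)
        a = _track(rng.poisson(20, 4000).astype(float))
        b = _track(rng.poisson(20, 4000).astype(float))
        r = cc.colocalization_matrix({"a": a, "b": b})["matrix"][0][1]
        assert abs(r) < 0.1

    def test_constant_track_flagged_absent(self):
        a = _track(np.full(100, 5.0))
        b = _track(np.random.default_rng(2).poisson(5, 100).astype(float))
        assert cc.colocalization_matrix({"a": a, "b": b})["matrix"][0][1] is None

    def test_peak_jaccard_identical_and_disjoint(self):
        p1 = cc.PeakSet("a", "sp", [cc.Peak(cc.Interval("chr1", 0, 100), 1, 50)])
        p2 = cc.PeakSet("b", "sp", [cc.Peak(cc.Interval("chr1", 0, 100), 1, 50)])
        p3 = cc.PeakSet("c", "sp", [cc.Peak(cc.Interval("chr1", 500, 600), 1, 550)])
        res = cc.colocalization_matrix({"a": p1, "b": p2, "c": p3})
        assert res["matrix"][0][1] == 1.0
        assert res["matrix"][0][2] == 0.0


class TestTeAssociation:
    def test_equal_occupancy_no_association(self):
        peaks = cc.PeakSet("m", "sp", [
            cc.Peak(cc.Interval("chr1", i * 1000, i * 1000 + 100), 1.0,
                    i * 1000 + 50) for i in range(0, 40, 2)
        ])
        with_te = [cc.Interval("chr1", i * 1000, (i + 1) * 1000)
                   for i in range(0, 20)]
        without_te = [cc.Interval("chr1", i * 1000, (i + 1) * 1000)
                      for i in range(20, 40)]
        res = cc.te_association_test(peaks, with_te, without_te)
        assert res.statistic < 1.0 and res.p_value > 0.3

    def test_empty_region_set_fails(self):
        peaks = cc.PeakSet("m", "sp", [])
        with pytest.raises(ValueError, match="non-empty"):
            cc.te_association_test(peaks, [], [cc.Interval("chr1", 0, 10)])


class TestMetaprofile:
    def _gene(self, strand="+"):
        return mk_gene("g", "chr1", 10_000, 15_000, strand)

    def test_constant_track_flat_profile(self):
        tr = _track(np.full(600, 7.0))
        mp = cc.metaprofile(tr, [self._gene()], flank_bp=2000, n_body_bins=100)
        norm = tr.normalized("chr1")[0]
        assert np.allclose(mp.profile, norm)

    def test_column_count(self):
        tr = _track(np.full(600, 1.0))
        mp = cc.metaprofile(tr, [self._gene()], flank_bp=2000, n_body_bins=100)
        assert mp.values.shape[1] == 2 * (2000 // 50) + 100

    def test_tss_peak_argmax_at_boundary(self):
        vals = np.full(600, 10.0)
        tr = _track(vals)
        gene = self._gene()
        for c in range(-8, 9):  # gaussian bump centred exactly at the TSS
            pos = gene.tss + c * 50 + 25
            tr.values["chr1"][pos // 50] += 80 * np.exp(-0.5 * (c * 50 / 100) ** 2)
        mp = cc.metaprofile(tr, [gene], flank_bp=2000, n_body_bins=100)
        assert abs(int(np.nanargmax(mp.profile)) - mp.tss_column) <= 1

    def test_strand_mirror_symmetry(self):
        rng = np.random.default_rng(3)
        vals = rng.poisson(20, 600).astype(float)
        fwd = _track(vals)
        rev = _track(vals[::-1])
        g_fwd = mk_gene("g", "chr1", 10_000, 15_000, "+")
        g_rev = mk_gene("g", "chr1", 30_000 - 15_000, 30_000 - 10_000, "-")
        mp_f = cc.metaprofile(fwd, [g_fwd], flank_bp=2000, n_body_bins=100)
        mp_r = cc.metaprofile(rev, [g_rev], flank_bp=2000, n_body_bins=100)
        assert np.allclose(mp_f.profile, mp_r.profile, equal_nan=True)


class TestDecileProfiles:
    def test_equal_group_sizes(self, default_dataset):
        ds = default_dataset
        tr = ds.tracks[("H3K4me3", "sp", 1)]
        genes = ds.annotation.genes[:100]
        tpm = ds.expression.mean_tpm("sp")
        profs = cc.decile_profiles(tr, genes, tpm, flank_bp=1000, n_body_bins=20)
        assert len(profs) == 10

    def test_fewer_than_ten_genes_fails(self, default_dataset):
        ds = default_dataset
        tr = ds.tracks[("H3K4me3", "sp", 1)]
        with pytest.raises(ValueError, match="10"):
            cc.decile_profiles(tr, ds.annotation.genes[:5],
                               ds.expression.mean_tpm("sp"))

    def test_coupled_mark_monotone_over_deciles(self, default_dataset):
        from scipy.stats import spearmanr
        ds = default_dataset
        tr = cc.average_tracks(ds.replicate_tracks("H3K4me3", "sp"))
        tpm = ds.expression.mean_tpm("sp")
        profs = cc.decile_profiles(tr, ds.annotation.genes, tpm,
                                   flank_bp=1000, n_body_bins=20)
        tss_col = 1000 // 50
        series = [p[tss_col] for p in profs]
        assert spearmanr(range(10), series).statistic >= 0.9


class TestGeneBodyPresence:
    def test_overlap_threshold(self):
        gene = mk_gene("g", "chr1", 1000, 2000, "+")
        below = cc.PeakSet("m", "sp", [cc.Peak(cc.Interval("chr1", 1000, 1200),
                                               1.0, 1100)])
        above = cc.PeakSet("m", "sp", [cc.Peak(cc.Interval("chr1", 1000, 1300),
                                               1.0, 1100)])
        assert not cc.gene_body_presence(below, [gene])["marked"]["g"]
        assert cc.gene_body_presence(above, [gene])["marked"]["g"]
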