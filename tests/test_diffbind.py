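import numpy as np
import pandas as pd
import pytest

from enhancekit import diffbind as db
from enhancekit.diffbind import CONTROL, TREATMENT, CountMatrix
from enhancekit.intervals import GenomicInterval, Peak


def make_matrix(counts, gc=None, libsizes=None):
    counts = np.asarray(counts, dtype=float)
    n, s = counts.shape
    assert s == 4
    peaks = [
        Peak(GenomicInterval("chr1", i * 1000, i * 1000 + 500), i * 1000 + 250, f"p{i}")
        for i in range(n)
    ]
    samples = pd.DataFrame(
        {
            "sample": ["C1", "C2", "L1", "L2"],
            "condition": [CONTROL, CONTROL, TREATMENT, TREATMENT],
            "replicate": [1, 2, 1, 2],
            "libsize": libsizes if libsizes is not None else counts.sum(axis=0),
        }
    )
    gc = np.full(n, 0.5) if gc is None else np.asarray(gc, dtype=float)
    return CountMatrix(peaks=peaks, samples=samples, counts=counts, gc=gc)


class TestNormalizeCounts:
    def test_identical_samples_unchanged_up_to_scale(self):
        rng = np.random.default_rng(0)
        col = rng.integers(1, 200, 50).astype(float)
        m = make_matrix(np.column_stack([col] * 4), gc=rng.beta(10, 10, 50))
        out = db.normalize_counts(m)
        ratio = out.counts / m.counts
        assert np.allclose(ratio, ratio[0, 0])

    def test_depth_scaling_equalizes_proportional_samples(self):
        rng = np.random.default_rng(1)
        col = rng.integers(1, 200, 40).astype(float)
        counts = np.column_stack([col, 2 * col, col, 2 * col])
        m = make_matrix(counts, libsizes=[1e6, 2e6, 1e6, 2e6])
        out = db.normalize_counts(m)
        assert np.allclose(out.counts[:, 0], out.counts[:, 1])
        assert np.allclose(out.counts[:, 2], out.counts[:, 3])

    def test_gc_flat_data_gc_step_is_identity(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 100, (30, 4)).astype(float)
        m = make_matrix(counts, gc=np.full(30, 0.5), libsizes=[1e6] * 4)
        out = db.normalize_counts(m)
        assert np.allclose(out.counts, counts)  # equal libsizes: scale factor 1

    def test_gc_bias_is_reduced(self):
        # sample L1 inflated at high GC: after correction the GC trend shrinks
        rng = np.random.default_rng(3)
        n = 500
        gc = rng.beta(10, 10, n)
        base = rng.lognormal(4, 0.3, n)
        counts = np.column_stack([base] * 4) * rng.normal(1, 0.05, (n, 4))
        counts[:, 2] *= np.exp(1.5 * (gc - 0.5))
        m = make_matrix(np.round(counts), gc=gc, libsizes=[1e6] * 4)
        out = db.normalize_counts(m)

        def gc_trend(c):
            hi, lo = gc > np.median(gc), gc <= np.median(gc)
            return np.log(c[hi, 2].mean() / c[hi, 0].mean()) - np.log(
                c[lo, 2].mean() / c[lo, 0].mean())

        assert abs(gc_trend(out.counts)) < 0.3 * abs(gc_trend(m.counts))

    def test_all_zero_sample_rejected(self):
        counts = np.ones((20, 4))
        counts[:, 1] = 0
        with pytest.raises(ValueError, match="all-zero"):
            db.normalize_counts(make_matrix(counts, libsizes=[1e6] * 4))

    def test_few_peaks_skip_gc_with_warning(self):
        m = make_matrix(np.ones((5, 4)), gc=np.linspace(0.2, 0.8, 5), libsizes=[1e6] * 4)
        with pytest.warns(UserWarning, match="GC"):
            db.normalize_counts(m)


class TestFoldOverRowMedian:
    def test_hand_computed_row(self):
        m = make_matrix([[10, 10, 20, 20]])
        r = db.fold_over_row_median(m)
        assert np.allclose(r.folds[0], [2 / 3, 2 / 3, 4 / 3, 4 / 3])

    def test_constant_row_gives_unit_folds(self):
        r = db.fold_over_row_median(make_matrix([[7, 7, 7, 7]]))
        assert np.allclose(r.folds[0], 1.0)

    def test_zero_row_is_degenerate(self):
        r = db.fold_over_row_median(make_matrix([[0, 0, 0, 0], [1, 1, 1, 1]]))
        assert r.degenerate[0] and not r.degenerate[1]
        assert np.all(r.folds[0] == 0)

    def test_divisor_is_mean_of_middle_order_statistics(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 100, (50, 4)).astype(float)
        r = db.fold_over_row_median(make_matrix(counts))
        for i in range(50):
            srt = np.sort(counts[i])
            divisor = (srt[1] + srt[2]) / 2  # even sample count
            assert np.allclose(r.folds[i], counts[i] / divisor)

    def test_normalization_invariance_of_folds(self):
        # scaling one sample's raw counts and libsize by c leaves folds unchanged
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 300, (40, 4)).astype(float)
        gc = rng.beta(10, 10, 40)
        lib = counts.sum(axis=0)
        r1 = db.fold_over_row_median(db.normalize_counts(make_matrix(counts, gc=gc, libsizes=lib)))
        c = 3.7
        counts2 = counts.copy()
        counts2[:, 2] *= c
        lib2 = lib.copy()
        lib2[2] *= c
        r2 = db.fold_over_row_median(db.normalize_counts(make_matrix(counts2, gc=gc, libsizes=lib2)))
        assert np.allclose(r1.folds, r2.folds, atol=1e-9)


class TestLog2FC:
    def test_two_fold_increase(self):
        m = make_matrix([[10, 10, 20, 20]])
        assert db.compute_log2fc(m, pseudocount=0)[0] == pytest.approx(1.0)

    def test_equal_means_zero(self):
        assert db.compute_log2fc(make_matrix([[5, 5, 5, 5]]))[0] == 0.0

    def test_zero_counts_with_pseudocount(self):
        assert db.compute_log2fc(make_matrix([[0, 0, 0, 0], [1, 1, 1, 1]]))[0] == 0.0


class TestSelection:
    def test_twofold_change_is_selected(self):
        m = make_matrix([[100, 100, 200, 200]])
        r = db.fold_over_row_median(m)
        assert list(db.select_variable_peaks(r, 1.5)) == [0]

    def test_small_change_not_selected(self):
        m = make_matrix([[100, 100, 120, 120]])
        r = db.fold_over_row_median(m)
        assert list(db.select_variable_peaks(r, 1.5)) == []

    def test_constant_matrix_selects_nothing(self):
        m = make_matrix(np.full((20, 4), 9.0))
        r = db.fold_over_row_median(m)
        assert len(db.select_variable_peaks(r)) == 0

    def test_decreases_also_selected(self):
        m = make_matrix([[200, 200, 90, 90]])
        r = db.fold_over_row_median(m)
        assert list(db.select_variable_peaks(r, 1.5)) == [0]


def blob_matrix(rng, n_per=30):
    """Four well-separated count patterns (C1, C2, L1, L2).

    Fold vectors over the row median: A ~ [0.29, 0.29, 1.71, 1.71] (both LPS
    replicates up — the only Group-1 candidate), B ~ [1, 1, 2.4, 0.8] (one
    replicate only), C ~ [1.5, 1.5, 0.5, 0.5] (decreased), D ~ [2.6, 1, 1, 1]
    (one control replicate up). Centroid mean LPS folds order A > B > D > C.
    """
    patterns = [
        (100, 100, 600, 600),
        (100, 100, 240, 80),
        (300, 300, 100, 100),
        (260, 100, 100, 100),
    ]
    rows = []
    for pat in patterns:
        rows.append(np.array(pat) * rng.normal(1, 0.02, (n_per, 4)))
    counts = np.vstack(rows)
    return make_matrix(counts, libsizes=[1e6] * 4), patterns


class TestClustering:
    def test_separated_blobs_recovered_and_relabelled(self):
        rng = np.random.default_rng(6)
        m, _ = blob_matrix(rng)
        r = db.fold_over_row_median(db.normalize_counts(m))
        sel = db.select_variable_peaks(r, 1.5)
        db.cluster_groups(r, sel, k=4, seed=0)
        labels = r.cluster[r.cluster > 0]
        # each blob is one cluster
        blocks = [r.cluster[i * 30 : (i + 1) * 30] for i in range(4)]
        for block in blocks:
            block = block[block > 0]
            assert len(np.unique(block)) == 1
        # cluster 1 = highest centroid mean LPS fold = the both-LPS-high blob
        assert np.all(blocks[0] == 1)
        assert len(np.unique(labels)) == 4

    def test_same_seed_is_deterministic(self):
        rng = np.random.default_rng(7)
        m, _ = blob_matrix(rng)
        r1 = db.fold_over_row_median(db.normalize_counts(m))
        sel = db.select_variable_peaks(r1, 1.5)
        db.cluster_groups(r1, sel, k=4, seed=123)
        r2 = db.fold_over_row_median(db.normalize_counts(m))
        db.select_variable_peaks(r2, 1.5)
        db.cluster_groups(r2, sel, k=4, seed=123)
        assert np.array_equal(r1.cluster, r2.cluster)

    def test_too_few_selected_raises(self):
        m = make_matrix([[100, 100, 300, 300]] * 3)
        r = db.fold_over_row_median(m)
        with pytest.raises(ValueError):
            db.cluster_groups(r, np.array([0, 1, 2]), k=4, seed=0)


class TestGroup1:
    def test_both_replicates_high_cluster_qualifies(self):
        rng = np.random.default_rng(8)
        m, _ = blob_matrix(rng)
        norm = db.normalize_counts(m)
        r = db.fold_over_row_median(norm)
        sel = db.select_variable_peaks(r, 1.5)
        db.cluster_groups(r, sel, k=4, seed=0)
        db.label_group1(r, 1.5)
        # exactly the both-LPS-high blob (centroid folds ~ [0.5,0.5,1.5,1.5])
        assert r.group1[:30].all()
        assert not r.group1[30:].any()

    def test_one_replicate_only_does_not_qualify(self):
        # L1 high but L2 clearly below the row median: no centroid can have
        # both LPS folds above 1
        rng = np.random.default_rng(9)
        counts = np.array([100, 100, 240, 80]) * rng.normal(1, 0.02, (40, 4))
        m = db.normalize_counts(make_matrix(counts, libsizes=[1e6] * 4))
        r = db.fold_over_row_median(m)
        sel = db.select_variable_peaks(r, 1.5)
        db.cluster_groups(r, sel, k=4, seed=0)
        with pytest.warns(UserWarning, match="Group 1"):
            db.label_group1(r, 1.5)
        assert not r.group1.any()

    def test_flat_data_has_no_group1(self):
        rng = np.random.default_rng(10)
        counts = np.full((30, 4), 100.0) * rng.normal(1, 0.3, (30, 4))
        m = db.normalize_counts(make_matrix(counts, libsizes=[1e6] * 4))
        r = db.fold_over_row_median(m)
        sel = db.select_variable_peaks(r, 1.5)
        if len(sel) >= 4:
            db.cluster_groups(r, sel, k=4, seed=0)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                db.label_group1(r, 1.5)
            # symmetric noise: nothing consistently increased in both replicates
            # may leak a few peaks, but direction must hold for all of them
            ctrl, trt = m.condition_columns(CONTROL), m.condition_columns(TREATMENT)
            assert np.all(
                m.counts[r.group1][:, trt].mean(axis=1) > m.counts[r.group1][:, ctrl].mean(axis=1)
            )

    def test_direction_consistency(self, small_dataset):
        m = db.normalize_counts(small_dataset.matrix)
        r = db.fold_over_row_median(m)
        sel = db.select_variable_peaks(r, 1.5)
        db.cluster_groups(r, sel, k=4, seed=0)
        db.label_group1(r, 1.5)
        ctrl, trt = m.condition_columns(CONTROL), m.condition_columns(TREATMENT)
        g1 = r.group1
        assert g1.any()
        assert np.all(m.counts[g1][:, trt].mean(axis=1) > m.counts[g1][:, ctrl].mean(axis=1))


class TestRankExtract:
    def test_linspace_medians_match_closed_form(self):
        n_peaks = 900
        lfc = np.linspace(-2, 2, n_peaks)
        m = make_matrix(np.column_stack([np.full(n_peaks, 100.0)] * 2
                                        + [100 * 2.0**lfc] * 2), libsizes=[1e6] * 4)
        r = db.fold_over_row_median(m)
        r.log2fc = lfc
        ranked = db.rank_extract(r, n=300)
        # top 300 of linspace(-2,2,900): median = (x_749 + x_750)/2 = 4*749.5/899 - 2
        expected = 4 * 749.5 / 899 - 2
        assert ranked.median_abs_log2fc["top"] == pytest.approx(expected, abs=1e-12)
        assert ranked.median_abs_log2fc["bottom"] == pytest.approx(expected, abs=1e-12)
        assert ranked.median_abs_log2fc["middle"] == pytest.approx(np.median(
            np.abs(np.sort(lfc)[::-1][300:600])), abs=1e-12)

    def test_sets_are_disjoint_permutation_slices(self):
        rng = np.random.default_rng(11)
        lfc = rng.normal(0, 1, 1000)
        m = make_matrix(np.ones((1000, 4)), libsizes=[1e6] * 4)
        r = db.fold_over_row_median(m)
        r.log2fc = lfc
        ranked = db.rank_extract(r, n=300)
        all_idx = np.concatenate([ranked.top, ranked.middle, ranked.bottom])
        assert len(set(all_idx.tolist())) == 900
        assert len(ranked.top) == len(ranked.middle) == len(ranked.bottom) == 300
        assert lfc[ranked.top].min() >= lfc[ranked.middle].max() >= lfc[ranked.bottom].max()

    def test_constant_log2fc_gives_zero_deviation(self):
        m = make_matrix(np.ones((900, 4)), libsizes=[1e6] * 4)
        r = db.fold_over_row_median(m)
        r.log2fc = np.zeros(900)
        ranked = db.rank_extract(r, n=300)
        assert set(ranked.median_abs_log2fc.values()) == {0.0}

    def test_too_few_peaks_raises(self):
        m = make_matrix(np.ones((100, 4)), libsizes=[1e6] * 4)
        r = db.fold_over_row_median(m)
        r.log2fc = np.zeros(100)
        with pytest.raises(ValueError):
            db.rank_extract(r, n=300)
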