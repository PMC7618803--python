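import numpy as np
import pytest

from hybridfod.evaluate import (
    ConnectivityMatrix,
    assign_fixels,
    atlas_probability_filter,
    bottleneck_mask,
    connectivity_matrix,
    crossing_fibre_ratio,
    density_map,
    log_correlation,
    outlier_filter,
    overlap_matrix,
    resample_streamline,
    roc_vs_reference,
)
from hybridfod.fod import grid_affine
from hybridfod.tracking import Tractogram


def straight(x0, x1, y=0.5, z=0.5, step=0.2):
    n = int(round((x1 - x0) / step)) + 1
    pts = np.zeros((n, 3))
    pts[:, 0] = x0 + step * np.arange(n)
    pts[:, 1] = y
    pts[:, 2] = z
    return pts


A1 = grid_affine(1.0)


class TestAtlasFilter:
    def make_map(self):
        pmap = np.zeros((10, 2, 2))
        pmap[:, 0, 0] = 1.0
        return pmap

    def test_high_probability_kept(self):
        t = Tractogram([straight(0.1, 8.9)])
        kept, counts = atlas_probability_filter(t, self.make_map(), A1)
        assert len(kept) == 1 and counts["kept"] == 1

    def test_low_probability_discarded(self):
        pmap = np.full((10, 2, 2), 0.1)
        t = Tractogram([straight(0.1, 8.9)])
        kept, counts = atlas_probability_filter(t, pmap, A1)
        assert len(kept) == 0 and counts["discarded_low_score"] == 1

    def test_boundary_mean_exactly_threshold_kept(self):
        """Voxel scores {0.3, 0.1} average to 0.2: the strict rule keeps it."""
        pmap = np.zeros((2, 1, 1))
        pmap[0, 0, 0] = 0.3
        pmap[1, 0, 0] = 0.1
        t = Tractogram([np.array([[0.5, 0.5, 0.5], [1.5, 0.5, 0.5]])])
        kept, _ = atlas_probability_filter(t, pmap, A1)
        assert len(kept) == 1

    def test_outside_map_counted_separately(self):
        t = Tractogram([straight(0.1, 8.9, y=50.0)])
        kept, counts = atlas_probability_filter(t, self.make_map(), A1)
        assert counts["discarded_outside"] == 1

    def test_idempotent(self):
        t = Tractogram([straight(0.1, 8.9), straight(0.1, 8.9, y=1.5)])
        once, _ = atlas_probability_filter(t, self.make_map(), A1)
        twice, _ = atlas_probability_filter(once, self.make_map(), A1)
        assert len(twice) == len(once)


class TestOutlierFilter:
    def test_identical_streamlines_untouched(self):
        t = Tractogram([straight(0, 10)] * 100)
        assert len(outlier_filter(t)) == 100

    def test_planted_length_outlier_removed(self):
        """49 equal streamlines plus one much longer: only it is removed."""
        base = [straight(0, 10.0 + 0.01 * i) for i in range(49)]
        long = straight(0, 40.0)
        t = Tractogram(base + [long])
        out = outlier_filter(t)
        assert len(out) == 49
        assert all(s[-1][0] < 39 for s in out.streamlines)

    def test_planted_deviation_outlier_removed(self):
        rng = np.random.default_rng(0)
        base = []
        for i in range(50):
            s = straight(0, 10)
            s[:, 1] += 0.01 * rng.normal(size=len(s))
            base.append(s)
        deviant = straight(0, 10, y=5.0)
        out = outlier_filter(Tractogram(base + [deviant]))
        assert len(out) == 50
        assert all(np.abs(s[:, 1]).max() < 1.0 for s in out.streamlines)

    def test_single_streamline_kept(self):
        t = Tractogram([straight(0, 10)])
        assert len(outlier_filter(t)) == 1

    def test_never_increases_and_idempotent(self):
        rng = np.random.default_rng(1)
        sls = [straight(0, 5 + 10 * rng.random()) for _ in range(30)]
        t = Tractogram(sls)
        once = outlier_filter(t)
        assert len(once) <= len(t)
        assert len(outlier_filter(once)) == len(once)

    def test_resample_preserves_endpoints(self):
        s = straight(0, 10)
        r = resample_streamline(s, 50)
        assert r.shape == (50, 3)
        assert np.allclose(r[0], s[0]) and np.allclose(r[-1], s[-1])


class TestDensityMap:
    def test_single_streamline_binary(self):
        d = density_map(Tractogram([straight(0.1, 4.9)]), (5, 2, 2), A1)
        assert set(np.unique(d)) <= {0.0, 1.0}
        assert d[:, 0, 0].sum() == 5

    def test_fractional_counts(self):
        sls = [straight(0.1, 0.9)] * 7 + [straight(0.1, 0.9, y=1.5)] * 3
        d = density_map(Tractogram(sls), (1, 2, 1), A1)
        assert np.isclose(d[0, 0, 0], 0.7)
        assert np.isclose(d[0, 1, 0], 0.3)
        assert d.max() <= 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            density_map(Tractogram([]), (2, 2, 2), A1)


class TestFixels:
    def peaks_x(self, shape):
        return {tuple(v): np.array([[1.0, 0, 0]]) for v in np.argwhere(np.ones(shape, bool))}

    def test_single_peak_everywhere_assigned(self):
        t = Tractogram([straight(0.1, 4.9)] * 3)
        fm = assign_fixels(t, self.peaks_x((5, 1, 1)), (5, 1, 1), A1)
        assert fm.unassigned_visits == 0
        total = sum(a.sum() for a in fm.density.values())
        assert np.isclose(total, 5.0)  # 5 voxels x density 1.0

    def test_best_alignment_wins(self):
        peaks = {(k, 0, 0): np.array([[0.0, 0, 1.0], [1.0, 0, 0]]) for k in range(5)}
        t = Tractogram([straight(0.1, 4.9)])
        fm = assign_fixels(t, peaks, (5, 1, 1), A1)
        for vox, dens in fm.density.items():
            assert dens[1] > 0 and dens[0] == 0

    def test_density_threshold_prunes(self):
        peaks = self.peaks_x((5, 1, 1))
        main = [straight(0.1, 4.9)] * 99
        stray = [np.array([[0.5, 0.5, 0.5], [0.7, 0.5, 0.5]])]  # visits 1 voxel once
        # make the stray its own fixel in an otherwise unvisited voxel
        peaks[(0, 0, 0)] = np.array([[1.0, 0, 0], [0.0, 0, 1.0]])
        fm = assign_fixels(Tractogram(main + stray), peaks, (5, 1, 1), A1)
        masked = fm.masked_fixels()
        assert all(d.max() > 0 for d in fm.density.values())
        # fixels below 5% of the max tract density are excluded from the mask
        low = [k for k, dens in fm.density.items() if 0 < dens.max() < 0.05 * 1.0]
        for vox in low:
            assert all((vox, fi) not in masked for fi in range(2))

    def test_no_peak_voxel_counts_unassigned(self):
        peaks = {}
        t = Tractogram([straight(0.1, 2.9)])
        fm = assign_fixels(t, peaks, (3, 1, 1), A1)
        assert fm.unassigned_visits == 3


class TestBottleneck:
    def fm(self, keys):
        dirs = {k: np.array([[1.0, 0, 0]]) for k, _ in keys}
        dens = {k: np.array([1.0]) for k, _ in keys}
        mask = {k: np.array([True]) for k, _ in keys}
        return type("FM", (), {"masked_fixels": lambda self_: set(keys)})()

    def test_disjoint_masks_no_bottleneck(self):
        a = self.fm([(((0, 0, 0)), 0)])
        b = self.fm([(((1, 0, 0)), 0)])
        multi, counts = bottleneck_mask([a, b])
        assert counts["multi_bundle"] == 0 and counts["single_bundle"] == 2

    def test_identical_masks_all_multi(self):
        keys = [((0, 0, 0), 0), ((1, 0, 0), 0)]
        multi, counts = bottleneck_mask([self.fm(keys), self.fm(keys)])
        assert counts["multi_bundle"] == 2 and counts["single_bundle"] == 0

    def test_requires_two_tracts(self):
        with pytest.raises(ValueError):
            bottleneck_mask([self.fm([])])


class TestCrossingRatio:
    def test_extremes_and_fraction(self):
        mask = np.ones((10, 1, 1), bool)
        assert crossing_fibre_ratio(np.ones((10, 1, 1)), mask) == 0.0
        assert crossing_fibre_ratio(np.full((10, 1, 1), 2), mask) == 1.0
        pc = np.ones((10, 1, 1))
        pc[:3] = 2
        assert np.isclose(crossing_fibre_ratio(pc, mask), 0.3)

    def test_no_fibre_signalled(self):
        with pytest.raises(ValueError):
            crossing_fibre_ratio(np.zeros((2, 1, 1)), np.ones((2, 1, 1), bool))


class TestConnectivity:
    def test_one_hot_row(self):
        labels = np.zeros((10, 1, 1), int)
        labels[9] = 3
        t = Tractogram([straight(0.5, 9.5)] * 4)
        m = connectivity_matrix({1: t}, labels, A1, [2, 3])
        assert np.allclose(m.values, [[0.0, 1.0]])

    def test_split_fractions(self):
        labels = np.zeros((10, 2, 1), int)
        labels[9, 0] = 2
        labels[9, 1] = 3
        sls = [straight(0.5, 9.5)] * 7 + [straight(0.5, 9.5, y=1.5)] * 3
        m = connectivity_matrix({1: Tractogram(sls)}, labels, A1, [2, 3])
        assert np.allclose(m.values, [[0.7, 0.3]])

    def test_rows_sum_at_most_one(self):
        labels = np.zeros((10, 1, 1), int)
        t = Tractogram([straight(0.5, 9.5)] * 5)  # never reaches a label
        m = connectivity_matrix({1: t}, labels, A1, [2])
        assert m.values.sum() == 0.0


def hand_matrices():
    ref = np.array([[2e-4, 0.0, 5e-5], [1e-3, 2e-3, 0.0], [0.0, 3e-4, 4e-4]])
    pred = np.array([[0.3, 0.0, 0.1], [0.2, 0.25, 0.0], [0.05, 0.15, 0.0]])
    return pred, ref


class TestRoc:
    def test_identity_gives_auc_one(self):
        rng = np.random.default_rng(2)
        ref = rng.random((5, 8)) * 0.2
        ref[ref < 0.05] = 0.0
        curve = roc_vs_reference(ref, ref, ref_threshold=1e-4)
        assert np.isclose(curve.auc, 1.0)
        assert any((t == 1.0) and (n == 1.0) for t, n in zip(curve.tpr, curve.tnr))

    def test_hand_computed_confusion_at_one_threshold(self):
        """3x3 example evaluated by hand at threshold 0.1: positives in the
        reference (>= 1e-4) are cells (0,0),(1,0),(1,1),(2,1),(2,2); the
        prediction calls (0,0),(1,0),(1,1),(2,1) (> 0.1)."""
        pred, ref = hand_matrices()
        curve = roc_vs_reference(pred, ref, pred_thresholds=np.array([0.1]))
        assert (curve.tp[0], curve.fp[0], curve.tn[0], curve.fn[0]) == (4, 0, 4, 1)
        assert np.isclose(curve.tpr[0], 4 / 5)
        assert np.isclose(curve.tnr[0], 1.0)

    def test_counts_sum_constant(self):
        pred, ref = hand_matrices()
        curve = roc_vs_reference(pred, ref)
        assert np.all(curve.tp + curve.fp + curve.tn + curve.fn == 9)

    def test_tpr_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        pred = rng.random((6, 6)) * 0.3
        ref = rng.random((6, 6)) * 1e-3
        ref[rng.random((6, 6)) < 0.4] = 0.0
        curve = roc_vs_reference(pred, ref)
        assert np.all(np.diff(curve.tpr) <= 1e-12)

    def test_permuted_predictions_auc_half(self):
        """Statistically independent predictions give AUC ~ 0.5."""
        rng = np.random.default_rng(4)
        ref = rng.random((10, 20)) * 1e-3
        ref[rng.random((10, 20)) < 0.5] = 0.0
        pred = rng.random((10, 20)) * 0.25
        aucs = []
        for _ in range(100):
            perm = rng.permutation(pred.size).reshape(pred.shape)
            aucs.append(roc_vs_reference(pred.flat[perm], ref).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_degenerate_reference_signalled(self):
        with pytest.raises(ValueError):
            roc_vs_reference(np.ones((2, 2)), np.ones((2, 2)))


class TestOverlap:
    def test_equal_matrices_no_mismatch(self):
        pred, ref = hand_matrices()
        cat, counts = overlap_matrix(ref, ref, pred_threshold=1e-4, ref_threshold=1e-4)
        assert counts["pred-only"] == 0 and counts["ref-only"] == 0

    def test_all_pred_only(self):
        cat, counts = overlap_matrix(np.ones((3, 3)), np.zeros((3, 3)), 0.5)
        assert counts["pred-only"] == 9 and counts["false_positive"] == 9

    def test_counts_match_set_algebra(self):
        rng = np.random.default_rng(5)
        pred = rng.integers(0, 2, (5, 5)).astype(float)
        ref = rng.integers(0, 2, (5, 5)).astype(float) * 1e-3
        cat, counts = overlap_matrix(pred, ref, pred_threshold=0.5, ref_threshold=1e-4)
        p, r = pred > 0.5, ref >= 1e-4
        assert counts["both"] == int((p & r).sum())
        assert counts["neither"] == int((~p & ~r).sum())
        assert sum(counts[k] for k in ("both", "pred-only", "ref-only", "neither")) == 25


class TestLogCorrelation:
    def test_identical_and_scaled_give_one(self):
        rng = np.random.default_rng(6)
        m = rng.random((4, 4)) * 0.2 + 1e-3
        rho, n = log_correlation(m, m, ref_floor=1e-6)
        assert np.isclose(rho, 1.0)
        rho2, _ = log_correlation(3.7 * m, m, ref_floor=1e-6)
        assert np.isclose(rho2, 1.0)

    def test_five_cell_hand_computation(self):
        """log10 pred = [-3,-2,-1,0,1], log10 ref = [-5,-4,-2,-1,-0.5]:
        rho = 12 / sqrt(10 * 15) = 0.9797958971132712."""
        pred = np.array([[1e-3, 1e-2, 1e-1, 1.0, 10.0]])
        ref = np.array([[1e-5, 1e-4, 1e-2, 1e-1, 10 ** -0.5]])
        rho, n = log_correlation(pred, ref, pred_floor=1e-4, ref_floor=1e-6)
        assert n == 5
        assert abs(rho - 12 / np.sqrt(150)) < 1e-12

    def test_floors_exclude_cells(self):
        pred = np.array([[1e-5, 0.1, 0.2, 0.3]])
        ref = np.array([[0.1, 1e-7, 0.2, 0.3]])
        with pytest.raises(ValueError):
            log_correlation(pred, ref)  # only 2 cells survive

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            log_correlation(np.ones((2, 2)), np.ones((3, 2)))
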