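"""Metric unit tests against independent brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist
from sklearn.metrics import precision_recall_fscore_support

from oarsort.eval_metrics import (
    classification_report,
    dice,
    hd95,
    msd,
    truncate_superior,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# brute-force oracle: all-pairs surface distances
# ---------------------------------------------------------------------------

def oracle_surface_points(mask, spacing):
    """Boundary voxels by explicit 6-neighbor check (independent of the
    implementation's erosion-based extraction)."""
    mask = np.asarray(mask, dtype=bool)
    pts = []
    for idx in np.argwhere(mask):
        for axis in range(3):
            for d in (-1, 1):
                nb = idx.copy()
                nb[axis] += d
                if (nb < 0).any() or (nb >= mask.shape).any() or not mask[tuple(nb)]:
                    pts.append(idx)
                    break
            else:
                continue
            break
    return np.asarray(pts, dtype=float) * np.asarray(spacing, dtype=float)


def oracle_distances(a, b, spacing):
    pa = oracle_surface_points(a, spacing)
    pb = oracle_surface_points(b, spacing)
    all_pairs = cdist(pa, pb)
    return all_pairs.min(axis=1), all_pairs.min(axis=0)


def oracle_hd95(a, b, spacing):
    d_ab, d_ba = oracle_distances(a, b, spacing)
    return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))


def oracle_msd(a, b, spacing):
    d_ab, d_ba = oracle_distances(a, b, spacing)
    return float((d_ab.mean() + d_ba.mean()) / 2.0)


def random_blob(rng, shape=(14, 14, 14)):
    center = rng.uniform(4, np.asarray(shape) - 4)
    radii = rng.uniform(2.0, 5.0, size=3)
    grids = np.indices(shape)
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return (acc <= 1.0).astype(np.uint8)


# ---------------------------------------------------------------------------
# dice
# ---------------------------------------------------------------------------

class TestDice:
    def test_identical_masks(self, rng):
        m = random_blob(rng)
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((6, 6, 6), dtype=np.uint8)
        b = np.zeros((6, 6, 6), dtype=np.uint8)
        a[1, 1, 1] = 1
        b[4, 4, 4] = 1
        assert dice(a, b) == 0.0

    def test_half_overlap_count_formula(self):
        # |A| = |B| = 8, |A∩B| = 4 -> 2*4/16 = 0.5
        a = np.zeros((4, 4, 4), dtype=np.uint8)
        b = np.zeros((4, 4, 4), dtype=np.uint8)
        a[0, 0, :2] = a[0, 1, :2] = a[1, 0, :2] = a[1, 1, :2] = 1
        b[0, 0, :2] = b[0, 1, :2] = 1
        b[2, 2, :2] = b[2, 3, :2] = 1
        assert int(a.sum()) == 8 and int(b.sum()) == 8
        assert int((a & b).sum()) == 4
        assert dice(a, b) == 0.5

    def test_both_empty_convention(self):
        z = np.zeros((3, 3, 3), dtype=np.uint8)
        assert dice(z, z) == 1.0

    def test_spacing_invariance(self, rng):
        a, b = random_blob(rng), random_blob(rng)
        assert dice(a, b) == dice(a, b)  # dice takes no spacing at all


# ---------------------------------------------------------------------------
# surface distances vs oracle
# ---------------------------------------------------------------------------

SPACINGS = [(1.0, 1.0, 1.0), (3.0, 2.0, 2.0), (2.5, 0.9766, 0.9766)]


class TestSurfaceDistances:
    @pytest.mark.parametrize("spacing", SPACINGS)
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_hd95_matches_brute_force(self, seed, spacing):
        rng = np.random.default_rng(seed)
        a, b = random_blob(rng), random_blob(rng)
        assert hd95(a, b, spacing) == pytest.approx(
            oracle_hd95(a, b, spacing), abs=1e-9
        )

    @pytest.mark.parametrize("spacing", SPACINGS)
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_msd_matches_brute_force(self, seed, spacing):
        rng = np.random.default_rng(seed)
        a, b = random_blob(rng), random_blob(rng)
        assert msd(a, b, spacing) == pytest.approx(
            oracle_msd(a, b, spacing), abs=1e-9
        )

    def test_identical_masks_zero(self, rng):
        m = random_blob(rng)
        assert hd95(m, m, (1, 1, 1)) == 0.0
        assert msd(m, m, (1, 1, 1)) == 0.0

    def test_one_voxel_shift_at_2mm(self):
        # every pooled surface distance equals one voxel = 2 mm
        a = np.zeros((3, 30, 30), dtype=np.uint8)
        b = np.zeros((3, 30, 30), dtype=np.uint8)
        a[1, 5, 5:25] = 1
        b[1, 6, 5:25] = 1
        spacing = (2.0, 2.0, 2.0)
        assert hd95(a, b, spacing) == pytest.approx(2.0)
        assert hd95(a, b, spacing) == pytest.approx(oracle_hd95(a, b, spacing))

    def test_parallel_planes_msd(self):
        # two single-voxel-thick planes 3 mm apart
        a = np.zeros((8, 5, 5), dtype=np.uint8)
        b = np.zeros((8, 5, 5), dtype=np.uint8)
        a[2] = 1
        b[3] = 1
        assert msd(a, b, (3.0, 1.0, 1.0)) == pytest.approx(3.0)

    def test_symmetry(self, rng):
        a, b = random_blob(rng), random_blob(rng)
        sp = (2.0, 1.0, 1.5)
        assert hd95(a, b, sp) == pytest.approx(hd95(b, a, sp), abs=1e-12)
        assert msd(a, b, sp) == pytest.approx(msd(b, a, sp), abs=1e-12)

    def test_isotropic_scaling_linearity(self, rng):
        a, b = random_blob(rng), random_blob(rng)
        assert hd95(a, b, (2, 2, 2)) == pytest.approx(2 * hd95(a, b, (1, 1, 1)))
        assert msd(a, b, (2, 2, 2)) == pytest.approx(2 * msd(a, b, (1, 1, 1)))

    def test_empty_mask_raises(self):
        z = np.zeros((4, 4, 4), dtype=np.uint8)
        m = np.ones((4, 4, 4), dtype=np.uint8)
        with pytest.raises(ValueError):
            hd95(z, m, (1, 1, 1))
        with pytest.raises(ValueError):
            msd(m, z, (1, 1, 1))


# ---------------------------------------------------------------------------
# superior truncation
# ---------------------------------------------------------------------------

class TestTruncateSuperior:
    def test_superior_slices_zeroed(self):
        truth = np.zeros((20, 4, 4), dtype=np.uint8)
        truth[5:11] = 1
        pred = np.zeros((20, 4, 4), dtype=np.uint8)
        pred[5:16] = 1  # extends 5 slices above truth
        out = truncate_superior(pred, truth)
        assert out[11:].sum() == 0
        assert np.array_equal(out[:11], pred[:11])

    def test_within_extent_identity(self):
        truth = np.zeros((10, 3, 3), dtype=np.uint8)
        truth[2:8] = 1
        pred = np.zeros((10, 3, 3), dtype=np.uint8)
        pred[3:6] = 1
        assert np.array_equal(truncate_superior(pred, truth), pred)

    @pytest.mark.parametrize("seed", range(6))
    def test_truncation_never_increases_hd95(self, seed):
        rng = np.random.default_rng(seed)
        truth = random_blob(rng)
        pred = random_blob(rng)
        # force an actual superior overhang
        pred[-2:] = truth[:2]
        truncated = truncate_superior(pred, truth)
        if not truncated.any():
            pytest.skip("degenerate draw")
        sp = (2.0, 1.0, 1.0)
        assert oracle_hd95(truncated, truth, sp) <= oracle_hd95(pred, truth, sp) + 1e-12


# ---------------------------------------------------------------------------
# wilcoxon
# ---------------------------------------------------------------------------

class TestWilcoxon:
    def test_n5_all_positive_exact(self):
        a = np.array([3.0, 4.0, 5.0, 6.0, 7.0])
        b = np.array([1.0, 1.5, 2.0, 2.5, 3.0])
        stat, p = wilcoxon_signed_rank(a, b)
        assert stat == 0.0
        assert p == pytest.approx(0.0625)  # 2/32 by enumeration

    def test_enumeration_matches_direct_count(self, rng):
        # independent oracle: enumerate all sign assignments explicitly
        d = rng.uniform(0.5, 3.0, size=7) * rng.choice([-1, 1], size=7)
        ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
        w_plus = ranks[d > 0].sum()
        sums = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([0, 1], repeat=7)
        ]
        sums = np.asarray(sums, dtype=float)
        expected = min(
            1.0,
            2.0 * min(np.mean(sums <= w_plus), np.mean(sums >= w_plus)),
        )
        _, p = wilcoxon_signed_rank(d, np.zeros_like(d))
        assert p == pytest.approx(expected, abs=1e-12)

    def test_identical_samples_raise(self):
        a = np.arange(6, dtype=float)
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(a, a)

    def test_two_sided_swap_invariance(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        _, p1 = wilcoxon_signed_rank(a, b)
        _, p2 = wilcoxon_signed_rank(b, a)
        assert p1 == pytest.approx(p2)

    def test_large_n_close_to_scipy(self, rng):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        a = rng.normal(0.4, 1.0, size=30)
        b = rng.normal(0.0, 1.0, size=30)
        _, p = wilcoxon_signed_rank(a, b)
        ref = scipy_wilcoxon(a, b, correction=True, mode="approx").pvalue
        assert p == pytest.approx(ref, rel=1e-6)


# ---------------------------------------------------------------------------
# classification report
# ---------------------------------------------------------------------------

VOCAB = ("A", "B", "Other")


class TestClassificationReport:
    def test_perfect_predictions(self):
        labels = ["A", "B", "Other", "A", "B"]
        report, cm = classification_report(labels, labels, VOCAB)
        assert report.accuracy == 1.0
        assert report.macro_f1 == 1.0
        assert np.all(np.diag(cm.counts) == cm.counts.sum(axis=1))

    def test_hand_computed_counts(self):
        # class A: TP=2, FP=0, FN=1 -> precision 1, recall 2/3, F1 0.8
        true = ["A", "A", "A", "B", "B"]
        pred = ["A", "A", "B", "B", "B"]
        report, _ = classification_report(true, pred, VOCAB)
        i = VOCAB.index("A")
        assert report.precision[i] == pytest.approx(1.0)
        assert report.recall[i] == pytest.approx(2 / 3)
        assert report.f1[i] == pytest.approx(0.8)

    def test_never_predicted_class_flagged_zero(self):
        true = ["A", "B", "Other"]
        pred = ["A", "A", "A"]
        report, _ = classification_report(true, pred, VOCAB)
        assert report.precision[VOCAB.index("B")] == 0.0
        assert "B" in report.zero_division_classes

    def test_matches_sklearn(self, rng):
        true = rng.choice(VOCAB, size=60).tolist()
        pred = rng.choice(VOCAB, size=60).tolist()
        report, _ = classification_report(true, pred, VOCAB)
        p, r, f, s = precision_recall_fscore_support(
            true, pred, labels=list(VOCAB), zero_division=0
        )
        np.testing.assert_allclose(report.precision, p)
        np.testing.assert_allclose(report.recall, r)
        np.testing.assert_allclose(report.f1, f)
        np.testing.assert_array_equal(report.support, s)
        pm, rm, fm, _ = precision_recall_fscore_support(
            true, pred, labels=list(VOCAB), average="macro", zero_division=0
        )
        assert report.macro_precision == pytest.approx(pm)
        pw, rw, fw, _ = precision_recall_fscore_support(
            true, pred, labels=list(VOCAB), average="weighted", zero_division=0
        )
        assert report.weighted_f1 == pytest.approx(fw)

    def test_unknown_label_raises(self):
        with pytest.raises(ValueError):
            classification_report(["A"], ["Z"], VOCAB)

    def test_row_normalized_confusion(self):
        true = ["A", "A", "B"]
        pred = ["A", "B", "B"]
        _, cm = classification_report(true, pred, VOCAB)
        norm = cm.normalized
        np.testing.assert_allclose(norm[0], [0.5, 0.5, 0.0])
        assert norm[2].sum() == 0.0  # empty row stays zero

    @given(st.lists(st.sampled_from(VOCAB), min_size=1, max_size=40))
    @settings(max_examples=40, deadline=None)
    def test_metrics_bounded(self, labels):
        rng = np.random.default_rng(len(labels))
        pred = rng.choice(VOCAB, size=len(labels)).tolist()
        report, cm = classification_report(labels, pred, VOCAB)
        for arr in (report.precision, report.recall, report.f1):
            assert np.all((arr >= 0) & (arr <= 1))
        assert 0 <= report.accuracy <= 1
        assert cm.counts.sum() == len(labels)
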