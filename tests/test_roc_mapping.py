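import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import auc_mann_whitney, roc_by_enumeration
from osteoflow.roc_mapping import PairedVoxelData, least_random_point, pool, roc_curve, superimpose
from osteoflow.stress_field import VoxelFieldSample
from osteoflow.uct_pipeline import BinaryMask


def _data(tau, labels, ids=None):
    tau = np.asarray(tau, dtype=float)
    ids = np.zeros(len(tau), dtype=int) if ids is None else ids
    return PairedVoxelData(tau, np.asarray(labels, dtype=bool), ids)


WORKED_TAU = np.array([1, 2, 3, 4, 5, 6]) * 1e-3  # Pa
WORKED_LABELS = np.array([0, 0, 1, 0, 1, 1], dtype=bool)


class TestWorkedExample:
    def test_auc_is_eight_ninths(self):
        curve = roc_curve(_data(WORKED_TAU, WORKED_LABELS))
        assert curve.auc == pytest.approx(8 / 9, abs=1e-12)
        assert curve.auc == pytest.approx(auc_mann_whitney(WORKED_TAU, WORKED_LABELS), abs=1e-12)

    def test_least_random_point_by_enumeration(self):
        curve = roc_curve(_data(WORKED_TAU, WORKED_LABELS))
        assert curve.tau_star == pytest.approx(3e-3)
        assert curve.tpr_star == pytest.approx(1.0)
        assert curve.fpr_star == pytest.approx(1 / 3)
        # cross-check every sweep point against exhaustive enumeration
        t, tpr, fpr = roc_by_enumeration(WORKED_TAU, WORKED_LABELS)
        assert np.allclose(curve.tpr, tpr) and np.allclose(curve.fpr, fpr)


class TestROCProperties:
    def test_curve_spans_unit_square_monotonically(self):
        rng = np.random.default_rng(0)
        d = _data(rng.exponential(1e-3, 500), rng.uniform(size=500) < 0.3)
        c = roc_curve(d)
        assert (c.tpr[0], c.fpr[0]) == (0.0, 0.0)
        assert (c.tpr[-1], c.fpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(c.tpr) >= 0) and np.all(np.diff(c.fpr) >= 0)

    def test_perfect_separation(self):
        tau = np.r_[np.full(5, 1e-3), np.full(5, 5e-3)]
        labels = np.r_[np.zeros(5, bool), np.ones(5, bool)]
        c = roc_curve(_data(tau, labels))
        assert c.auc == 1.0
        assert (c.tpr_star, c.fpr_star) == (1.0, 0.0)

    def test_matches_sklearn_on_random_instances(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(1)
        for _ in range(25):
            n = rng.integers(20, 200)
            tau = np.round(rng.exponential(2e-3, n), 4)  # force ties
            labels = rng.uniform(size=n) < 0.4
            if labels.all() or not labels.any():
                continue
            ours = roc_curve(_data(tau, labels)).auc
            assert ours == pytest.approx(roc_auc_score(labels, tau), abs=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.tuples(st.floats(1e-6, 1e-2), st.booleans()), min_size=4, max_size=60))
    def test_invariant_under_monotone_transform(self, records):
        tau = np.array([r[0] for r in records])
        labels = np.array([r[1] for r in records])
        if labels.all() or not labels.any():
            return
        a = roc_curve(_data(tau, labels))
        b = roc_curve(_data(np.log(tau) + 5.0, labels))
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        assert a.tpr_star == pytest.approx(b.tpr_star) and a.fpr_star == pytest.approx(b.fpr_star)

    def test_flipping_top_negative_never_decreases_auc(self):
        rng = np.random.default_rng(2)
        tau = rng.exponential(1e-3, 200)
        labels = rng.uniform(size=200) < 0.5
        base = roc_curve(_data(tau, labels)).auc
        flipped = labels.copy()
        neg_idx = np.nonzero(~labels)[0]
        flipped[neg_idx[np.argmax(tau[neg_idx])]] = True
        assert roc_curve(_data(tau, flipped)).auc >= base - 1e-12

    def test_degenerate_classes_rejected(self):
        with pytest.raises(ValueError):
            roc_curve(_data([1.0, 2.0], [True, True]))


class TestLeastRandomPoint:
    def test_tie_broken_toward_larger_threshold(self):
        # two sweep points share the maximal J; the larger tau must win
        tau = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array([False, True, False, True])
        c = roc_curve(_data(tau, labels))
        j = c.tpr - c.fpr
        winners = c.thresholds[j == j.max()]
        assert c.tau_star == winners.max()
        assert least_random_point(c)[0] == c.tau_star


class TestSuperimposeAndPool:
    def _sample(self, tau3d, valid=None):
        tau3d = np.asarray(tau3d, dtype=float)
        valid = np.ones(tau3d.shape, bool) if valid is None else valid
        return VoxelFieldSample(np.where(valid, tau3d, np.nan), 36e-6,
                                np.zeros(3), valid)

    def test_counts(self):
        shape = (10, 10, 10)
        rng = np.random.default_rng(3)
        ss = self._sample(rng.uniform(0, 1e-2, shape))
        mineral = BinaryMask(np.arange(1000).reshape(shape) < 10, 36e-6)
        region = BinaryMask(np.ones(shape, bool), 36e-6)
        d = superimpose(ss, mineral, region, sample_id="s1")
        assert (d.p, d.n_neg, d.n_excluded) == (10, 990, 0)

    def test_invalid_voxels_excluded_and_tallied(self):
        shape = (6, 6, 6)
        valid = np.ones(shape, bool)
        valid[0, :, :] = False
        ss = self._sample(np.full(shape, 1e-3), valid)
        region = BinaryMask(np.ones(shape, bool), 36e-6)
        mineral = BinaryMask(np.zeros(shape, bool), 36e-6)
        mineral.data[5, 5, 5] = True
        d = superimpose(ss, mineral, region)
        assert d.n_excluded == 36
        assert d.n == 216 - 36

    def test_lattice_mismatch_rejected(self):
        ss = self._sample(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            superimpose(ss, BinaryMask(np.zeros((5, 4, 4), bool), 36e-6),
                        BinaryMask(np.zeros((4, 4, 4), bool), 36e-6))

    def test_pool_identity_and_sums(self):
        rng = np.random.default_rng(4)
        a = _data(rng.uniform(0, 1, 50), rng.uniform(size=50) < 0.5, np.full(50, 0))
        b = _data(rng.uniform(0, 1, 30), rng.uniform(size=30) < 0.5, np.full(30, 1))
        assert pool([a]).n == a.n
        pooled = pool([a, b])
        assert pooled.p == a.p + b.p
        assert pooled.n_neg == a.n_neg + b.n_neg

    def test_pooling_order_invariant(self):
        rng = np.random.default_rng(5)
        parts = [_data(rng.uniform(0, 1, 40), rng.uniform(size=40) < 0.4, np.full(40, i))
                 for i in range(3)]
        c1 = roc_curve(pool(parts))
        c2 = roc_curve(pool(parts[::-1]))
        assert c1.auc == pytest.approx(c2.auc, abs=1e-14)
        assert c1.tau_star == c2.tau_star

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            pool([])
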