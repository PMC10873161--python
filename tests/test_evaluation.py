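import numpy as np
import pytest

from cellfactor.data_io import (
    CellLabelMap,
    GeneExpressionMatrix,
    GroundTruthTable,
    LRDatabaseTable,
    LRRecord,
)
from cellfactor.errors import DegenerateTruthError, ValidationError
from cellfactor.evaluation import (
    SpotTable,
    binarize_mean,
    lr_global_correlation,
    roc_auc,
    spatial_truth,
)
from cellfactor.network import TypeCommMatrix


def type_matrix(strengths, labels=None):
    strengths = np.asarray(strengths, dtype=float)
    labels = labels or [chr(ord("a") + i) for i in range(strengths.shape[0])]
    thr = strengths.mean()
    return TypeCommMatrix(labels, strengths, thr, strengths > thr)


def brute_force_auc(scores, truth):
    """Concordant-pair counting over all positive x negative pairs."""
    pos = [s for p, s in scores.items() if truth.records[p]]
    neg = [s for p, s in scores.items() if not truth.records[p]]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


class TestBinarize:
    def test_mean_threshold_example(self):
        t = type_matrix([[1.0, 2.0], [3.0, 4.0]])
        # mean 2.5 -> ones at 3 and 4
        np.testing.assert_array_equal(binarize_mean(t), [[0, 0], [1, 1]])

    def test_flattened_example_with_mean_3p2(self):
        # strengths {1,2,3,4,6}: mean 3.2, ones at {4,6}
        t = type_matrix(np.array([[1.0, 2.0, 3.0], [4.0, 6.0, 3.2], [3.2, 3.2, 3.2]]))
        b = binarize_mean(t)
        assert b[1, 0] == 1 and b[1, 1] == 1
        assert b[0].sum() == 0

    def test_constant_matrix_all_zero(self):
        assert binarize_mean(type_matrix(np.full((2, 2), 5.0))).sum() == 0

    def test_agrees_with_significance_flags(self, rng):
        t = type_matrix(rng.random((4, 4)))
        np.testing.assert_array_equal(binarize_mean(t), t.significant.astype(int))


class TestRocAuc:
    def test_perfect_separation(self):
        scores = {("a", "b"): 0.9, ("b", "a"): 0.9, ("a", "c"): 0.1, ("c", "a"): 0.1}
        truth = GroundTruthTable(
            {("a", "b"): True, ("b", "a"): True, ("a", "c"): False, ("c", "a"): False}
        )
        assert roc_auc(scores, truth).auc == pytest.approx(1.0)

    def test_all_ties_give_half(self):
        scores = {("a", "b"): 0.5, ("b", "a"): 0.5, ("a", "c"): 0.5}
        truth = GroundTruthTable(
            {("a", "b"): True, ("b", "a"): False, ("a", "c"): False}
        )
        assert roc_auc(scores, truth).auc == pytest.approx(0.5)

    def test_six_pair_exhaustive_oracle(self):
        pairs = [("s", f"t{i}") for i in range(6)]
        scores = dict(zip(pairs, [5.0, 4.0, 3.0, 2.0, 1.0, 0.0]))
        truth = GroundTruthTable(
            {p: s in {5.0, 3.0, 1.0} for p, s in scores.items()}
        )
        result = roc_auc(scores, truth)
        assert result.auc == pytest.approx(brute_force_auc(scores, truth), abs=1e-9)

    def test_random_tables_match_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 12))
            pairs = [("s", f"t{i}") for i in range(n)]
            scores = {p: float(rng.integers(0, 5)) for p in pairs}  # ties likely
            flags = rng.random(n) < 0.5
            if flags.all() or not flags.any():
                flags[0] = not flags[0]
            truth = GroundTruthTable(dict(zip(pairs, map(bool, flags))))
            result = roc_auc(scores, truth)
            assert result.auc == pytest.approx(brute_force_auc(scores, truth), abs=1e-9)

    def test_monotone_transform_invariance(self, rng):
        pairs = [("s", f"t{i}") for i in range(8)]
        scores = {p: float(rng.random()) for p in pairs}
        truth = GroundTruthTable({p: i % 2 == 0 for i, p in enumerate(pairs)})
        a1 = roc_auc(scores, truth).auc
        a2 = roc_auc({p: np.exp(3 * s) for p, s in scores.items()}, truth).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_negated_scores_complement(self, rng):
        pairs = [("s", f"t{i}") for i in range(9)]
        scores = {p: float(i) for i, p in enumerate(pairs)}  # tie-free
        truth = GroundTruthTable({p: i % 3 == 0 for i, p in enumerate(pairs)})
        a = roc_auc(scores, truth).auc
        b = roc_auc({p: -s for p, s in scores.items()}, truth).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_curve_endpoints_and_monotonicity(self, rng):
        pairs = [("s", f"t{i}") for i in range(10)]
        scores = {p: float(rng.random()) for p in pairs}
        truth = GroundTruthTable({p: i < 4 for i, p in enumerate(pairs)})
        r = roc_auc(scores, truth)
        assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
        assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)

    def test_single_class_truth_rejected(self):
        scores = {("a", "b"): 1.0, ("b", "a"): 0.0}
        with pytest.raises(DegenerateTruthError):
            roc_auc(scores, GroundTruthTable({("a", "b"): True, ("b", "a"): True}))

    def test_uncovered_pair_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc({("a", "b"): 1.0}, GroundTruthTable({("x", "y"): True}))


class TestSpatialTruth:
    def test_two_adjacent_spots(self):
        spots = SpotTable(["s1", "s2"], np.array([[0.0, 0.0], [1.0, 0.0]]), ["a", "b"])
        truth = spatial_truth(spots)
        assert truth.records[("a", "b")] and truth.records[("b", "a")]

    def test_far_singleton_is_unsupported(self):
        spots = SpotTable(
            ["s1", "s2", "s3"],
            np.array([[0.0, 0.0], [1.0, 0.0], [50.0, 50.0]]),
            ["a", "b", "c"],
        )
        truth = spatial_truth(spots)
        assert not any(
            flag for (x, y), flag in truth.records.items() if "c" in (x, y)
        )

    def test_hexagonal_grid_center_has_six_neighbors(self):
        angles = np.arange(6) * np.pi / 3
        xy = np.vstack([[0.0, 0.0], np.column_stack([np.cos(angles), np.sin(angles)])])
        labels = ["center"] + [f"ring{i}" for i in range(6)]
        truth = spatial_truth(SpotTable(labels, xy, labels), neighbor_factor=1.5)
        center_partners = {
            y for (x, y), flag in truth.records.items() if flag and x == "center" and y != "center"
        }
        assert len(center_partners) == 6
        # each ring spot touches the center and its two ring neighbors only
        ring_partners = {
            y for (x, y), flag in truth.records.items() if flag and x == "ring0" and y != "ring0"
        }
        assert ring_partners == {"center", "ring1", "ring5"}

    def test_single_label_rejected(self):
        spots = SpotTable(["s1", "s2"], np.array([[0.0, 0.0], [1.0, 0.0]]), ["a", "a"])
        with pytest.raises(DegenerateTruthError):
            spatial_truth(spots)


class TestLRGlobalCorrelation:
    def expr_and_labels(self, rng):
        vals = rng.random((4, 9)) + 0.2
        expr = GeneExpressionMatrix(
            ["L1", "R1", "L2", "R2"], [f"c{j}" for j in range(9)], vals
        )
        labels = CellLabelMap.from_pairs(
            [(f"c{j}", ["a", "b", "c"][j // 3]) for j in range(9)]
        )
        return expr, labels

    def test_proportional_scores_give_r_one(self, rng):
        expr, labels = self.expr_and_labels(rng)
        db = LRDatabaseTable([LRRecord(("L1",), ("R1",)), LRRecord(("L2",), ("R2",))])
        # build a type matrix exactly proportional to the coexpression score
        idx = labels.type_indices(expr.cell_ids)
        from cellfactor.lr import collapse_complex

        score = np.zeros((3, 3))
        for rec in db.records:
            lm = [collapse_complex(expr, rec.ligand_subunits)[idx[t]].mean() for t in "abc"]
            rm = [collapse_complex(expr, rec.receptor_subunits)[idx[t]].mean() for t in "abc"]
            score += np.outer(lm, rm)
        score /= 2
        t = type_matrix(2.5 * score, ["a", "b", "c"])
        r, p = lr_global_correlation(t, expr, labels, db)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_empty_database_rejected(self, rng):
        expr, labels = self.expr_and_labels(rng)
        t = type_matrix(rng.random((3, 3)), ["a", "b", "c"])
        with pytest.raises(ValidationError):
            lr_global_correlation(t, expr, labels, LRDatabaseTable([]))
        with pytest.raises(ValidationError):
            lr_global_correlation(
                t, expr, labels, LRDatabaseTable([LRRecord(("nope",), ("R1",))])
            )

    def test_constant_scores_degenerate(self, rng):
        expr, labels = self.expr_and_labels(rng)
        expr.values[:] = 1.0  # all coexpression scores identical
        db = LRDatabaseTable([LRRecord(("L1",), ("R1",))])
        t = type_matrix(rng.random((3, 3)), ["a", "b", "c"])
        with pytest.warns(UserWarning):
            r, p = lr_global_correlation(t, expr, labels, db)
        assert (r, p) == (0.0, 1.0)

    def test_planted_dataset_has_positive_correlation(self):
        from cellfactor.pipeline import analyze
        from cellfactor.simulate import make_planted_dataset

        hits = 0
        for seed in range(1, 6):
            expr, labels, truth = make_planted_dataset(seed, 40, 60, 2, 1, 0.3)
            res = analyze(expr, labels, seed=seed)
            db = LRDatabaseTable(
                [LRRecord((lig,), (rec,)) for lig, rec, _, _ in truth.planted_lr_pairs]
            )
            r, _ = lr_global_correlation(res.type_comm, res.expr, labels, db)
            hits += r > 0
        assert hits >= 4
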