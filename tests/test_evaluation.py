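import numpy as np
import pytest

from gtbind.evaluation import (
    confusion_and_metrics,
    full_report,
    nonlocal_contact_counts,
    optimal_threshold_by_mcc,
    paired_structure_comparison,
    pr_auc,
    roc_auc,
    stratified_metrics,
)
from gtbind.structure_io import ProteinRecord
from gtbind.synthetic import generate_backbone


def _scores_for_counts(TP, FP, FN, TN):
    """Labels/scores realizing a target confusion matrix at threshold 0.5."""
    y = np.r_[np.ones(TP), np.zeros(FP), np.ones(FN), np.zeros(TN)]
    s = np.r_[np.full(TP, 0.9), np.full(FP, 0.9),
              np.full(FN, 0.1), np.full(TN, 0.1)]
    return y.astype(int), s


class TestConfusionMetrics:
    def test_worked_example(self):
        y, s = _scores_for_counts(TP=16, FP=3, FN=12, TN=266)
        rep = confusion_and_metrics(y, s, 0.5)
        assert (rep.TP, rep.FP, rep.FN, rep.TN) == (16, 3, 12, 266)
        assert rep.Pre == pytest.approx(16 / 19)
        assert rep.Rec == pytest.approx(16 / 28)
        assert rep.ACC == pytest.approx(282 / 297)
        assert rep.n == 297

    def test_perfect_predictor(self):
        y = np.array([0, 1, 0, 1, 1])
        rep = confusion_and_metrics(y, y.astype(float), 0.5)
        for name in ("ACC", "Pre", "Rec", "Spe", "F1", "MCC"):
            assert getattr(rep, name) == 1.0
        assert rep.degenerate == []

    def test_balanced_coin_has_zero_mcc(self):
        y, s = _scores_for_counts(TP=1, FP=1, FN=1, TN=1)
        rep = confusion_and_metrics(y, s, 0.5)
        assert rep.MCC == 0.0
        assert "MCC" not in rep.degenerate

    def test_degenerate_denominators_flagged_as_zero(self):
        # nothing predicted positive -> Pre and F1 undefined
        y = np.array([1, 0, 0])
        s = np.array([0.1, 0.1, 0.2])
        rep = confusion_and_metrics(y, s, 0.9)
        assert rep.Pre == 0.0 and rep.F1 == 0.0 and rep.MCC == 0.0
        assert {"Pre", "MCC"} <= set(rep.degenerate)

    def test_threshold_is_geq(self):
        y = np.array([1, 0])
        s = np.array([0.5, 0.4])
        rep = confusion_and_metrics(y, s, 0.5)
        assert rep.TP == 1  # score == threshold counts as positive

    def test_input_validation(self):
        with pytest.raises(ValueError):
            confusion_and_metrics([0, 2], [0.5, 0.5], 0.5)
        with pytest.raises(ValueError):
            confusion_and_metrics([0, 1], [0.5, 1.5], 0.5)

    def test_matches_naive_recomputation_randomized(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(2, 100))
            y = rng.integers(0, 2, size=n)
            s = np.round(rng.random(n), 2)
            t = float(rng.random())
            rep = confusion_and_metrics(y, s, t)
            pred = (s >= t).astype(int)
            TP = np.sum((pred == 1) & (y == 1))
            FP = np.sum((pred == 1) & (y == 0))
            FN = np.sum((pred == 0) & (y == 1))
            TN = np.sum((pred == 0) & (y == 0))
            den = np.sqrt(float(TP + FP) * (TP + FN) * (TN + FP) * (TN + FN))
            want = (TP * TN - FN * FP) / den if den else 0.0
            assert rep.MCC == pytest.approx(want, abs=1e-12)

    def test_mcc_invariant_under_class_relabeling(self):
        """Swapping the positive/negative convention together with score
        reflection leaves MCC unchanged."""
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, size=60)
        s = rng.random(60)
        t = 0.37
        a = confusion_and_metrics(y, s, t).MCC
        b = confusion_and_metrics(1 - y, 1 - s, 1 - t).MCC
        # score>=t complements to score<=t; no score equals t a.s.
        assert a == pytest.approx(b, abs=1e-12)


class TestRankMetrics:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        assert roc_auc(y, y.astype(float)) == 1.0
        assert pr_auc(y, y.astype(float)) == 1.0

    def test_constant_scores_give_half_auc(self):
        y = np.array([0, 1, 0, 1])
        assert roc_auc(y, np.full(4, 0.5)) == 0.5

    def test_pair_counting_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            y = rng.integers(0, 2, size=50)
            y[:2] = [0, 1]
            s = np.round(rng.random(50), 2)  # force some ties
            pos, neg = s[y == 1], s[y == 0]
            gt = (pos[:, None] > neg[None, :]).sum()
            eq = (pos[:, None] == neg[None, :]).sum()
            want = (gt + 0.5 * eq) / (len(pos) * len(neg))
            assert roc_auc(y, s) == pytest.approx(want, abs=1e-9)

    def test_auprc_at_least_prevalence_for_any_ordering(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, size=80)
        y[:2] = [0, 1]
        prevalence = y.mean()
        assert pr_auc(y, y.astype(float)) >= prevalence
        # random scores: AUPRC ~ prevalence in expectation
        vals = [pr_auc(y, rng.random(80)) for _ in range(60)]
        assert np.mean(vals) == pytest.approx(prevalence, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.ones(5, dtype=int), np.random.rand(5))


class TestThresholdSelection:
    def test_separable_example_returns_midpoint(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.8, 0.9])
        assert optimal_threshold_by_mcc(y, s) == pytest.approx(0.5)

    def test_anti_predictor_max_mcc_nonpositive(self):
        y = np.array([0, 0, 1, 1, 0, 1])
        s = 1.0 - y.astype(float)
        t = optimal_threshold_by_mcc(y, s)
        assert confusion_and_metrics(y, s, t).MCC <= 0.0

    def test_dense_grid_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            y = rng.integers(0, 2, size=40)
            y[:2] = [0, 1]
            s = np.round(rng.random(40), 2)
            t = optimal_threshold_by_mcc(y, s)
            best = confusion_and_metrics(y, s, t).MCC
            grid_best = max(confusion_and_metrics(y, s, g).MCC
                            for g in np.linspace(0, 1, 500))
            assert best >= grid_best - 1e-12


class TestNonlocalContacts:
    def test_straight_chain_has_none(self):
        X = np.column_stack([np.arange(50) * 3.8, np.zeros(50), np.zeros(50)])
        np.testing.assert_array_equal(nonlocal_contact_counts(X), 0)

    def test_boundary_is_strict(self):
        # residues 0 and 25: separation 25 (> 20), distance exactly 12.0
        X = np.zeros((26, 3))
        X[:, 0] = np.arange(26) * 1000.0  # keep everything else far apart
        X[25] = [12.0, 0.0, 0.0]
        counts = nonlocal_contact_counts(X)
        assert counts[0] == 0 and counts[25] == 0

    def test_matches_bruteforce_on_compact_cluster(self):
        X = generate_backbone(60, seed=5)
        counts = nonlocal_contact_counts(X)
        brute = np.array([
            sum(1 for j in range(60)
                if abs(i - j) > 20 and np.linalg.norm(X[i] - X[j]) < 12.0)
            for i in range(60)
        ])
        np.testing.assert_array_equal(counts, brute)
        assert counts.max() >= 1  # collapsed walks do have nonlocal contacts
        # symmetry: i counts j iff j counts i (total count is even)
        assert counts.sum() % 2 == 0


class TestStratification:
    bins = ((0, 10), (10, 20), (20, None))

    def test_all_in_first_bin(self):
        y = np.array([0, 1, 0, 1])
        s = np.array([0.1, 0.9, 0.2, 0.8])
        out = stratified_metrics(y, s, np.zeros(4, int), 0.5, self.bins)
        assert out[0]["n_residues"] == 4
        assert out[1]["flag"] == "empty" and out[2]["flag"] == "empty"

    def test_partition_totals(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, size=100)
        s = rng.random(100)
        counts = rng.integers(0, 40, size=100)
        out = stratified_metrics(y, s, counts, 0.5, self.bins)
        assert sum(e["n_residues"] for e in out) == 100

    def test_per_bin_equals_subset_recomputation(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, size=200)
        s = rng.random(200)
        counts = rng.integers(0, 30, size=200)
        out = stratified_metrics(y, s, counts, 0.4, self.bins)
        for entry in out:
            lo, hi = entry["bin"]
            mask = (counts >= lo) & ((counts < hi) if hi is not None else True)
            if entry["n_residues"]:
                want = confusion_and_metrics(y[mask], s[mask], 0.4)
                assert entry["report"].MCC == pytest.approx(want.MCC)

    def test_bad_bins_rejected(self):
        with pytest.raises(ValueError):
            stratified_metrics([0, 1], [0.1, 0.9], [0, 1], 0.5,
                               bins=((0, 10), (12, None)))
        with pytest.raises(ValueError):
            stratified_metrics([0, 1], [0.1, 0.9], [0, 1], 0.5,
                               bins=((0, 10), (10, 20)))


def _geometry_predictor(rec):
    """Rotation-invariant stand-in predictor: squashed contact counts."""
    c = nonlocal_contact_counts(rec.ca_coords)
    return 1.0 / (1.0 + np.exp(-(c - c.mean())))


class TestPairedComparison:
    def _records(self, n_prot=4, seed=0):
        recs, labels = [], {}
        rng = np.random.default_rng(seed)
        for i in range(n_prot):
            X = generate_backbone(40, seed=seed * 10 + i)
            rec = ProteinRecord(id=f"p{i}", sequence="A" * 40, ca_coords=X)
            recs.append(rec)
            y = rng.integers(0, 2, size=40)
            y[:2] = [0, 1]
            labels[rec.id] = y
        return recs, labels

    def test_identical_sets_zero_change(self):
        recs, labels = self._records()
        out = paired_structure_comparison(
            _geometry_predictor, recs, recs, labels, threshold=0.5)
        for v in out["relative_change"].values():
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_zero_change(self):
        from scipy.spatial.transform import Rotation
        recs, labels = self._records(seed=1)
        R = Rotation.random(random_state=np.random.RandomState(2)).as_matrix()
        moved = [ProteinRecord(id=r.id, sequence=r.sequence,
                               ca_coords=r.ca_coords @ R.T + 4.0)
                 for r in recs]
        out = paired_structure_comparison(
            _geometry_predictor, recs, moved, labels, threshold=0.5)
        for v in out["relative_change"].values():
            assert v == pytest.approx(0.0, abs=1e-9)

    def test_jittered_copies_report_finite_change(self):
        recs, labels = self._records(seed=2)
        rng = np.random.default_rng(3)
        jittered = [ProteinRecord(id=r.id, sequence=r.sequence,
                                  ca_coords=r.ca_coords
                                  + rng.normal(scale=1.0, size=(40, 3)))
                    for r in recs]
        out = paired_structure_comparison(
            _geometry_predictor, recs, jittered, labels, threshold=0.5)
        assert np.isfinite(list(out["relative_change"].values())).all()
        assert out["bound"].n == out["unbound"].n == 160

    def test_unpaired_ids_rejected(self):
        recs, labels = self._records()
        with pytest.raises(ValueError, match="unpaired"):
            paired_structure_comparison(
                _geometry_predictor, recs, recs[:-1], labels, threshold=0.5)

    def test_length_mismatch_rejected(self):
        recs, labels = self._records()
        short = [ProteinRecord(id=recs[0].id, sequence="A" * 39,
                               ca_coords=recs[0].ca_coords[:39])] + recs[1:]
        with pytest.raises(ValueError, match="mismatch"):
            paired_structure_comparison(
                _geometry_predictor, recs, short, labels, threshold=0.5)


def test_full_report_includes_rank_metrics():
    y = np.array([0, 1, 0, 1, 1, 0])
    s = np.array([0.2, 0.8, 0.3, 0.9, 0.7, 0.6])
    rep = full_report(y, s)
    assert rep.AUC is not None and rep.AUPRC is not None
    assert 0 < rep.threshold < 1
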