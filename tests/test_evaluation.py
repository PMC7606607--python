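"""Fold plans, the Mann-Whitney AUC, Greiner bands and cross-validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from sibbn.evaluation import (
    FoldPlan,
    auc,
    classify_auc,
    cross_validate,
    kfold_split,
)
from sibbn.synthetic_data import generate

from .conftest import auc_pairwise


class TestKFold:
    def test_study_scale_fold_sizes(self):
        plan = kfold_split(328, 10, seed=0)
        sizes = sorted(np.bincount(plan.assignment))
        assert sizes == [32, 32] + [33] * 8

    def test_leave_one_out(self):
        plan = kfold_split(10, 10, seed=1)
        assert sorted(np.bincount(plan.assignment)) == [1] * 10

    def test_seed_determinism_and_partition(self):
        a = kfold_split(57, 7, seed=42)
        b = kfold_split(57, 7, seed=42)
        assert a.assignment == b.assignment
        assert set(a.assignment) == set(range(7))
        assert kfold_split(57, 7, seed=43).assignment != a.assignment

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            kfold_split(5, 6)
        with pytest.raises(ValueError):
            kfold_split(5, 1)


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_label_antisymmetry(self):
        assert auc([0.9, 0.8, 0.7, 0.6], [0, 0, 1, 1]) == 0.0

    def test_constant_scores_are_chance(self):
        assert auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pairwise_oracle_and_trapezoid(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 40))
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        got = auc(scores, labels)
        assert abs(got - auc_pairwise(scores, labels)) < 1e-12
        assert abs(got - roc_auc_score(labels, scores)) < 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            auc([0.1, 0.2], [1, 1])

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(
        st.tuples(st.floats(0, 1, allow_nan=False), st.booleans()),
        min_size=4, max_size=30,
    ).filter(lambda rows: 0 < sum(y for _, y in rows) < len(rows)))
    def test_label_flip_antisymmetry_and_range(self, rows):
        """Flipping every label reflects the AUC about ½, and the value is
        always a valid probability."""
        scores = [s for s, _ in rows]
        labels = [int(y) for _, y in rows]
        a = auc(scores, labels)
        assert 0.0 <= a <= 1.0
        flipped = auc(scores, [1 - y for y in labels])
        assert a + flipped == pytest.approx(1.0, abs=1e-12)


class TestGreinerBands:
    @pytest.mark.parametrize("value,label", [
        (0.55, "less accurate"),
        (0.84, "moderately accurate"),
        (1.0, "perfect"),
        (0.5, "poor"),
        (0.3, "poor"),
        (0.7, "less accurate"),     # 0.7 excluded from "moderately"
        (0.9, "moderately accurate"),
        (0.95, "highly accurate"),
    ])
    def test_banding(self, value, label):
        assert classify_auc(value) == label

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_auc(1.2)


class TestCrossValidate:
    def test_signal_beats_chance_and_null_is_chance(self):
        bundle = generate("1B", n=328, poc_missing=49, seed=5)
        report = cross_validate("1B", bundle.table, k=10, seed=5)
        assert report.auc > 0.55
        # permute outcomes independently of the features
        rng = np.random.default_rng(5)
        recs = [dict(r) for r in bundle.table.records]
        outcomes = [r["ecoli_pou"] for r in recs]
        for r, o in zip(recs, rng.permutation(outcomes)):
            r["ecoli_pou"] = o
        from sibbn.learning import SurveyTable
        null = cross_validate("1B", SurveyTable(recs), k=10, seed=5)
        assert abs(null.auc - 0.5) < 0.12
        assert report.auc > null.auc

    def test_record_order_invariance(self):
        """Permuting the records while permuting the fold plan the same way
        leaves the pooled scores, labels and AUC unchanged."""
        bundle = generate("1A", n=120, poc_missing=15, seed=9)
        n = len(bundle.table)
        plan = kfold_split(n, 5, seed=3)
        base = cross_validate("1A", bundle.table, seed=3, plan=plan)
        rng = np.random.default_rng(0)
        perm = rng.permutation(n)
        from sibbn.learning import SurveyTable
        permuted = SurveyTable([bundle.table.records[i] for i in perm])
        pplan = FoldPlan(k=5, assignment=tuple(
            plan.assignment[i] for i in perm))
        alt = cross_validate("1A", permuted, seed=3, plan=pplan)
        assert alt.auc == pytest.approx(base.auc, abs=1e-12)
        assert sorted(zip(alt.scores, alt.labels)) == pytest.approx(
            sorted(zip(base.scores, base.labels)))

    def test_fullness_adds_predictive_information(self):
        """Observing storage fullness improves discrimination whenever the
        truth wires it into the outcome: the paired AUC gain from revealing
        fullness (scoring with the generating network itself, which isolates
        the information content from CPT-estimation noise) is positive in
        mean across seeds."""
        from sibbn.inference import predict_outcome
        from sibbn.si_model import ECOLI_POU, FULLNESS
        diffs = []
        for seed in range(6):
            bundle = generate("1B", n=800, poc_missing=0, seed=seed)
            truth = bundle.truth
            labels = [int(r[ECOLI_POU] == "detected")
                      for r in bundle.table.records]
            cache = {}

            def score(rec, drop):
                key = (tuple(sorted(
                    (k, v) for k, v in rec.items() if k != ECOLI_POU)), drop)
                if key not in cache:
                    r = dict(rec)
                    if drop:
                        r[FULLNESS] = None
                    cache[key] = predict_outcome(
                        truth, r, ECOLI_POU, "detected")
                return cache[key]

            with_f = auc([score(r, False) for r in bundle.table.records],
                         labels)
            without = auc([score(r, True) for r in bundle.table.records],
                          labels)
            diffs.append(with_f - without)
        assert np.mean(diffs) > 0

    def test_missing_outcome_records_excluded(self):
        bundle = generate("1A", n=80, poc_missing=10, seed=1)
        recs = [dict(r) for r in bundle.table.records]
        recs[0]["ecoli_pou"] = None
        from sibbn.learning import SurveyTable
        with pytest.warns(UserWarning, match="lack the outcome"):
            report = cross_validate("1A", SurveyTable(recs), k=5, seed=1)
        assert len(report.scores) == 79
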