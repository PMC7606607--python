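"""Cross-validated AUC assessment of a model variant.

Validation follows the standard protocol: a seeded k-fold split (k = 10 by
default), per-fold EM refitting on the training folds, held-out records
scored by the posterior probability of the designated outcome state with
the outcome excluded from the evidence, all held-out scores pooled, and a
single AUC computed against the observed outcomes.  The AUC is the
Mann–Whitney probability that a random positive outscores a random
negative, ties counted half.  Qualitative labels follow Greiner's bands:
poor (≤0.5), less accurate (0.5–0.7], moderately accurate (0.7–0.9],
highly accurate (0.9–1), perfect (1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .bn_core import NetworkSpec
from .inference import predict_outcome
from .learning import SurveyTable, em_fit
from .si_model import ECOLI_POU, ModelVariant, build_model

__all__ = [
    "FoldPlan",
    "ValidationReport",
    "kfold_split",
    "cross_validate",
    "auc",
    "classify_auc",
]


@dataclass(frozen=True)
class FoldPlan:
    """A k-fold partition: fold id per record index."""

    k: int
    assignment: tuple[int, ...]
    seed: int | None = None

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.assignment) == fold)


def kfold_split(n: int, k: int, seed: int | None = None) -> FoldPlan:
    """Seeded shuffle then contiguous partition; fold sizes differ by ≤1."""
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    assignment = np.empty(n, dtype=int)
    start = 0
    for fold, size in enumerate(sizes):
        assignment[perm[start:start + size]] = fold
        start += size
    return FoldPlan(k=k, assignment=tuple(int(x) for x in assignment), seed=seed)


def auc(scores, labels) -> float:
    """Mann–Whitney AUC: P(score⁺ > score⁻) + ½·P(tie).

    ``labels`` are binary (1 = positive class); both classes must occur.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length vectors")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    ranks = rankdata(scores)  # average ranks handle ties as ½
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def classify_auc(a: float) -> str:
    """Greiner's qualitative accuracy band for an AUC value."""
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"AUC out of range: {a}")
    if a == 1.0:
        return "perfect"
    if a > 0.9:
        return "highly accurate"
    if a > 0.7:
        return "moderately accurate"
    if a > 0.5:
        return "less accurate"
    return "poor"


@dataclass
class ValidationReport:
    """Pooled cross-validation outcome: AUC, its band, and raw scores."""

    auc: float
    accuracy_class: str
    scores: np.ndarray
    labels: np.ndarray
    fold_of: np.ndarray
    roc_points: np.ndarray = field(default=None)  # (fpr, tpr) rows

    def summary(self) -> str:
        return (
            f"k-fold cross-validation: AUC = {self.auc:.3f} "
            f"({self.accuracy_class}); {len(self.scores)} pooled records, "
            f"{int(self.labels.sum())} positive"
        )


def cross_validate(variant: ModelVariant | str | NetworkSpec, data: SurveyTable,
                   k: int = 10, seed: int | None = None,
                   outcome: str = ECOLI_POU, positive_state: str = "detected",
                   score_state: str | None = None,
                   stratified: bool = False,
                   plan: FoldPlan | None = None,
                   **em_settings) -> ValidationReport:
    """k-fold cross-validated AUC of one model variant on a survey table.

    Each fold's model is re-initialized and EM-fitted on the other k−1
    folds; held-out records are scored by P(outcome = score_state | their
    non-missing fields).  ``score_state`` defaults to ``positive_state``
    so that higher scores mean the positive (detected) class.  Records
    with a missing outcome are excluded from scoring.  ``stratified``
    balances outcome classes across folds.
    """
    if isinstance(variant, NetworkSpec):
        structure = variant
    else:
        structure = build_model(ModelVariant.parse(variant))
    score_state = score_state or positive_state
    usable = [i for i, r in enumerate(data.records)
              if r.get(outcome) is not None]
    if len(usable) < len(data.records):
        warnings.warn(
            f"{len(data.records) - len(usable)} records lack the outcome "
            f"and are excluded from validation scoring"
        )
    n = len(usable)
    if plan is not None:
        if len(plan.assignment) != n:
            raise ValueError("fold plan does not match usable record count")
    elif stratified:
        labs = np.array(
            [data.records[i][outcome] == positive_state for i in usable]
        )
        assignment = np.empty(n, dtype=int)
        rng_seed = seed
        for cls in (True, False):
            idx = np.flatnonzero(labs == cls)
            sub = kfold_split(len(idx), min(k, len(idx)), seed=rng_seed)
            assignment[idx] = sub.assignment
        plan = FoldPlan(k=k, assignment=tuple(int(x) for x in assignment),
                        seed=seed)
    else:
        plan = kfold_split(n, k, seed=seed)
    k = plan.k

    scores = np.empty(n)
    labels = np.empty(n, dtype=int)
    fold_of = np.asarray(plan.assignment)
    for fold in range(k):
        test_pos = plan.fold_indices(fold)
        train_rows = [data.records[usable[i]] for i in range(n)
                      if fold_of[i] != fold]
        fit = em_fit(structure, SurveyTable(train_rows),
                     init="uniform", **em_settings)
        for i in test_pos:
            rec = data.records[usable[i]]
            scores[i] = predict_outcome(fit.network, rec, outcome, score_state)
            labels[i] = int(rec[outcome] == positive_state)
    # orient scores so the AUC refers to the positive class
    oriented = scores if score_state == positive_state else 1.0 - scores
    a = auc(oriented, labels)
    fpr, tpr, _ = roc_curve(labels, oriented)
    return ValidationReport(
        auc=a,
        accuracy_class=classify_auc(a),
        scores=scores,
        labels=labels,
        fold_of=fold_of,
        roc_points=np.column_stack([fpr, tpr]),
    )
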