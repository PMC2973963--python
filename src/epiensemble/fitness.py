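"""Ensemble fitness of a candidate factor subset.

A subset is scored by an M-classifier committee through three components on
a common [0, 1] scale, combined as a weighted sum:

    fitness = w1 * blocking + w2 * voting + w3 * diversity

* blocking — mean balanced accuracy of the individual classifiers (every
  classifier sees the same data split, so differences reflect the subset,
  not the split);
* voting — balanced accuracy of the majority-vote consensus prediction;
* diversity — one minus the mean pairwise double-fault rate (the fraction
  of samples misclassified by both members of a pair).

Predictions come from stratified k-fold cross-validation with pooled
out-of-fold predictions; the fold assignment is seeded and shared across all
classifiers and all subsets evaluated under one configuration, so subset
scores are paired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import classifiers as clf
from .data import CASE, CONTROL, GenotypeMatrix, PhenotypeLabels


@dataclass(frozen=True)
class EnsembleConfig:
    """Committee composition, integration weights, and evaluation protocol.

    The default weights (0.425 blocking, 0.425 voting, 0.15 diversity) are
    the tuned setting under which the five-member committee outperformed the
    best single classifier.
    """

    specs: tuple[clf.ClassifierSpec, ...] = None  # type: ignore[assignment]
    w_blocking: float = 0.425
    w_voting: float = 0.425
    w_diversity: float = 0.15
    n_folds: int = 5
    protocol_seed: int = 0

    def __post_init__(self) -> None:
        if self.specs is None:
            object.__setattr__(self, "specs", tuple(clf.default_ensemble_specs()))
        if len(self.specs) < 2:
            raise ValueError("the ensemble needs at least two classifiers")
        w = (self.w_blocking, self.w_voting, self.w_diversity)
        if any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")

    @property
    def n_classifiers(self) -> int:
        return len(self.specs)


@dataclass(frozen=True)
class PredictionSet:
    """Pooled cross-validated predictions of every committee member."""

    predictions: np.ndarray  # (M, N) predicted labels
    truth: np.ndarray        # (N,) true labels
    classifier_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.predictions.shape[1] != self.truth.shape[0]:
            raise ValueError("prediction/truth length mismatch")

    @property
    def n_classifiers(self) -> int:
        return self.predictions.shape[0]

    @property
    def prior_label(self) -> int:
        return CASE if (self.truth == CASE).sum() * 2 > self.truth.size else CONTROL


@dataclass(frozen=True)
class FitnessBreakdown:
    """The three fitness components and their weighted combination."""

    blocking: float
    voting: float
    diversity: float
    combined: float
    subset_size: int

    def __post_init__(self) -> None:
        for v in (self.blocking, self.voting, self.diversity, self.combined):
            if not -1e-12 <= v <= 1 + 1e-12:
                raise ValueError("fitness components must lie in [0, 1]")


def balanced_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """(sensitivity + specificity) / 2, on the 0-100 scale.

    Se = 100 * N_TP / N_case and Sp = 100 * N_TN / N_control, which keeps the
    score honest under imbalanced case-control ratios.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    n_case = int((truth == CASE).sum())
    n_control = int((truth == CONTROL).sum())
    if n_case == 0 or n_control == 0:
        raise ValueError("truth must contain both classes")
    se = 100.0 * ((pred == CASE) & (truth == CASE)).sum() / n_case
    sp = 100.0 * ((pred == CONTROL) & (truth == CONTROL)).sum() / n_control
    return (se + sp) / 2.0


def consensus_size(m: int) -> int:
    """Votes needed for a majority-vote consensus among M classifiers."""
    if m < 1:
        raise ValueError("M must be >= 1")
    return m // 2 + 1 if m % 2 == 0 else (m + 1) // 2


def majority_vote(ps: PredictionSet) -> np.ndarray:
    """Per-sample consensus label; an exact even split falls back to the prior."""
    case_votes = (ps.predictions == CASE).sum(axis=0)
    control_votes = ps.n_classifiers - case_votes
    out = np.where(case_votes > control_votes, CASE, CONTROL).astype(np.int8)
    out[case_votes == control_votes] = ps.prior_label
    return out


def fitness_blocking(ps: PredictionSet) -> float:
    """Mean per-classifier balanced accuracy, rescaled to [0, 1]."""
    bcs = [balanced_accuracy(p, ps.truth) for p in ps.predictions]
    return float(np.mean(bcs)) / 100.0


def fitness_voting(ps: PredictionSet) -> float:
    """Balanced accuracy of the majority-vote prediction, rescaled to [0, 1]."""
    if ps.n_classifiers < 2:
        raise ValueError("voting needs at least two classifiers")
    return balanced_accuracy(majority_vote(ps), ps.truth) / 100.0


def pairwise_double_fault(
    pred_a: np.ndarray, pred_b: np.ndarray, truth: np.ndarray
) -> float:
    """Fraction of samples misclassified by both classifiers."""
    pred_a, pred_b, truth = np.asarray(pred_a), np.asarray(pred_b), np.asarray(truth)
    if not pred_a.shape == pred_b.shape == truth.shape:
        raise ValueError("length mismatch")
    return float(((pred_a != truth) & (pred_b != truth)).mean())


def fitness_diversity(ps: PredictionSet) -> float:
    """1 minus the mean pairwise double-fault rate over all classifier pairs.

    Equals 1 when no sample is misclassified by any pair and 0 when every
    classifier misclassifies every sample.
    """
    m = ps.n_classifiers
    if m < 2:
        raise ValueError("diversity needs at least two classifiers")
    wrong = ps.predictions != ps.truth[None, :]
    total = 0.0
    for a in range(m):
        for b in range(a + 1, m):
            total += float((wrong[a] & wrong[b]).mean())
    return 1.0 - total * 2.0 / (m * (m - 1))


def combined_fitness(
    blocking: float, voting: float, diversity: float, config: EnsembleConfig,
    subset_size: int = 0,
) -> FitnessBreakdown:
    """Weighted combination of the three components."""
    combined = (
        config.w_blocking * blocking
        + config.w_voting * voting
        + config.w_diversity * diversity
    )
    return FitnessBreakdown(blocking, voting, diversity, combined, subset_size)


# ---------------------------------------------------------------------------
# Cross-validated evaluation


def _stratified_folds(
    labels: np.ndarray, n_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    n_minority = min(int((labels == CASE).sum()), int((labels == CONTROL).sum()))
    if n_folds > n_minority:
        warnings.warn(
            f"reducing folds from {n_folds} to {n_minority} to keep both "
            "classes in every fold",
            stacklevel=3,
        )
        n_folds = max(2, n_minority)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros_like(labels), labels)]


class EnsembleEvaluator:
    """Scores factor subsets of one dataset under a fixed protocol, with caching.

    Folds are computed once from the protocol seed, so every subset (and every
    restart of a search sharing this evaluator) is evaluated on identical
    splits and scores are directly comparable.
    """

    def __init__(
        self,
        data: GenotypeMatrix,
        labels: PhenotypeLabels,
        config: EnsembleConfig | None = None,
    ):
        self.config = config or EnsembleConfig()
        self.data = data
        self.values = np.ascontiguousarray(data.values, dtype=np.int16)
        self.truth = labels.labels
        self.folds = _stratified_folds(
            self.truth, self.config.n_folds, self.config.protocol_seed
        )
        self._cache: dict[frozenset[int], FitnessBreakdown] = {}
        self.n_evaluations = 0
        self._train_rows = np.concatenate([tr for tr, _ in self.folds])
        self._train_roots = np.concatenate(
            [np.full(tr.size, i, dtype=np.intp) for i, (tr, _) in enumerate(self.folds)]
        )
        self._test_rows = np.concatenate([te for _, te in self.folds])
        self._test_roots = np.concatenate(
            [np.full(te.size, i, dtype=np.intp) for i, (_, te) in enumerate(self.folds)]
        )

    def predictions(self, subset: Sequence[int]) -> PredictionSet:
        """Pooled out-of-fold predictions of every committee member on a subset."""
        cols = np.asarray(sorted(subset), dtype=int)
        x = self.values[:, cols]
        n = x.shape[0]
        m = self.config.n_classifiers
        preds = np.empty((m, n), dtype=np.int8)
        tree_idx = [i for i, s in enumerate(self.config.specs) if s.kind == clf.DECISION_TREE]
        other = [(i, s) for i, s in enumerate(self.config.specs)
                 if s.kind != clf.DECISION_TREE]
        # all folds' trees grow and route together as one forest
        for i in tree_idx:
            spec = self.config.specs[i]
            forest = clf._grow_forest(
                x[self._train_rows],
                self.truth[self._train_rows],
                roots=self._train_roots,
                n_roots=len(self.folds),
                max_depth=spec.max_depth,
            )
            preds[i, self._test_rows] = forest.route(
                x[self._test_rows], self._test_roots
            )
        knn_items = [(i, s.k) for i, s in other if s.kind == clf.KNN]
        kstar_items = [(i, s.blend) for i, s in other if s.kind == clf.KSTAR]
        for tr, te in self.folds:
            x_tr, x_te, y_tr = x[tr], x[te], self.truth[tr]
            prior = CASE if (y_tr == CASE).sum() * 2 > y_tr.size else CONTROL
            fold_preds = clf.fold_instance_predictions(
                x_te, x_tr, y_tr, knn_items, kstar_items, prior
            )
            for i, p in fold_preds.items():
                preds[i, te] = p
        return PredictionSet(
            preds, self.truth, tuple(s.identifier for s in self.config.specs)
        )

    def evaluate(self, subset: Sequence[int]) -> FitnessBreakdown:
        key = frozenset(int(c) for c in subset)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        ps = self.predictions(subset)
        self.n_evaluations += 1
        fb = combined_fitness(
            fitness_blocking(ps),
            fitness_voting(ps),
            fitness_diversity(ps),
            self.config,
            subset_size=len(key),
        )
        self._cache[key] = fb
        return fb


def cross_validated_predictions(
    data: GenotypeMatrix,
    subset: Sequence[str],
    labels: PhenotypeLabels,
    config: EnsembleConfig | None = None,
) -> PredictionSet:
    """Convenience wrapper: evaluate a subset given by factor ids."""
    evaluator = EnsembleEvaluator(data, labels, config)
    cols = [data.factor_ids.index(f) for f in subset]
    if not cols:
        raise ValueError("subset must be non-empty")
    return evaluator.predictions(cols)
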