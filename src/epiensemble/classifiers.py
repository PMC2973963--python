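"""Base classifiers for categorical genotype features.

The ensemble uses five members: a gain-ratio decision tree, an entropic
instance-based learner (KStar-style), and exact k-nearest-neighbour with
k in {1, 3, 5}.  Genotypes are treated as unordered categories; kNN uses the
overlap (Hamming) distance.  Every tie-break is fixed so that training and
prediction are fully deterministic:

* tree leaves: majority class, ties to control;
* tree splits: highest gain ratio, ties to the lowest factor index, and a
  split is made even at zero gain while the node is impure and a factor with
  more than one observed value remains;
* kNN: neighbours ordered by (distance, training-row index); vote ties go to
  the training class prior (prior ties to control);
* KStar: class-summed transformation probabilities, ties to the prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .data import CASE, CONTROL, GenotypeMatrix, PhenotypeLabels

DECISION_TREE = "decision_tree"
KNN = "knn"
KSTAR = "kstar"


@dataclass(frozen=True)
class ClassifierSpec:
    """Which base learner to build, with its parameters."""

    kind: str
    k: int = 1                # knn neighbourhood size
    blend: float = 0.20       # kstar match/transform mixing weight
    max_depth: int | None = None
    identifier: str = ""

    def __post_init__(self) -> None:
        if self.kind not in (DECISION_TREE, KNN, KSTAR):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.kind == KNN and self.k < 1:
            raise ValueError("k must be >= 1")
        if self.kind == KSTAR and not 0.0 < self.blend < 1.0:
            raise ValueError("blend must be in (0, 1)")
        if not self.identifier:
            name = {DECISION_TREE: "tree", KSTAR: "kstar"}.get(self.kind, f"{self.k}nn")
            object.__setattr__(self, "identifier", name)


def default_ensemble_specs() -> list[ClassifierSpec]:
    """The five-member committee: tree, KStar, and 1/3/5-nearest-neighbour."""
    return [
        ClassifierSpec(DECISION_TREE, identifier="J48"),
        ClassifierSpec(KSTAR, identifier="KStar"),
        ClassifierSpec(KNN, k=1, identifier="CT1NN"),
        ClassifierSpec(KNN, k=3, identifier="CT3NN"),
        ClassifierSpec(KNN, k=5, identifier="CT5NN"),
    ]


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    factor_ids: tuple[str, ...]
    prior_case_fraction: float
    state: object = field(repr=False, default=None)

    @property
    def prior_label(self) -> int:
        # strict majority of cases wins; ties go to control
        return CASE if self.prior_case_fraction > 0.5 else CONTROL


def _as_arrays(
    train: GenotypeMatrix | np.ndarray, labels: PhenotypeLabels | np.ndarray
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    if isinstance(train, GenotypeMatrix):
        x = train.values
        ids = tuple(train.factor_ids)
    else:
        x = np.asarray(train, dtype=np.int16)
        ids = tuple(f"f{j}" for j in range(x.shape[1]))
    y = labels.labels if isinstance(labels, PhenotypeLabels) else np.asarray(labels)
    return x, np.asarray(y, dtype=np.int8), ids


def fit(
    spec: ClassifierSpec,
    train: GenotypeMatrix | np.ndarray,
    labels: PhenotypeLabels | np.ndarray,
) -> TrainedModel:
    """Train one base classifier on a (restricted) factor matrix."""
    x, y, ids = _as_arrays(train, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class training data")
    prior = float((y == CASE).mean())
    if spec.kind == DECISION_TREE:
        state = _grow_forest(x, y, max_depth=spec.max_depth)
    elif spec.kind == KNN:
        state = (x.copy(), y.copy())
    else:
        state = (x.copy(), y.copy(), _kstar_level_probs(x))
    return TrainedModel(spec, ids, prior, state)


def predict(model: TrainedModel, test: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Predict case/control labels for the test rows."""
    if isinstance(test, GenotypeMatrix):
        if tuple(test.factor_ids) != model.factor_ids:
            raise ValueError("test factors do not match the trained model")
        x = test.values
    else:
        x = np.asarray(test, dtype=np.int16)
        if x.ndim != 2 or x.shape[1] != len(model.factor_ids):
            raise ValueError("test factor-count mismatch")
    if x.shape[0] == 0:
        return np.empty(0, dtype=np.int8)
    spec = model.spec
    if spec.kind == DECISION_TREE:
        return model.state.route(x)  # type: ignore[union-attr]
    if spec.kind == KNN:
        xt, yt = model.state  # type: ignore[misc]
        order = knn_neighbor_order(x, xt)
        return knn_vote(order, yt, spec.k, model.prior_label)
    xt, yt, level_probs = model.state  # type: ignore[misc]
    return _kstar_predict(x, xt, yt, level_probs, spec.blend, model.prior_label)


# ---------------------------------------------------------------------------
# Gain-ratio decision tree (multiway categorical splits)


_INV_LN2 = 1.0 / np.log(2.0)
_XLOGX_TABLE = special.xlogy(np.arange(2048), np.arange(2048)) * _INV_LN2


def _xlogx(c: np.ndarray) -> np.ndarray:
    """x * log2(x) elementwise with 0 log 0 = 0; table lookup for small ints."""
    if c.dtype.kind in "iu" and c.size and int(c.max()) < _XLOGX_TABLE.size:
        return _XLOGX_TABLE[c]
    return special.xlogy(c, c) * _INV_LN2


@dataclass
class DecisionForest:
    """One gain-ratio tree per root, stored level-wise in flat arrays.

    Level record d holds, for every node at depth d: the factor it splits on
    (-1 for a leaf), its majority label, and a (node, factor value) -> child
    index map into level d+1.  Growing and routing all trees of a
    cross-validation round together keeps the work vectorised.
    """

    levels: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    n_roots: int

    def route(self, x: np.ndarray, roots: np.ndarray | None = None) -> np.ndarray:
        """Majority label of the leaf each row reaches from its root.

        A factor value never seen at a split node stops there with that
        node's majority label.
        """
        n = x.shape[0]
        out = np.empty(n, dtype=np.int8)
        cur = np.zeros(n, dtype=np.intp) if roots is None else roots.astype(np.intp)
        alive = np.arange(n)
        for factor, majority, child_map in self.levels:
            is_leaf = factor[cur] < 0
            out[alive[is_leaf]] = majority[cur[is_leaf]]
            alive, cur = alive[~is_leaf], cur[~is_leaf]
            if alive.size == 0:
                break
            vals = x[alive, factor[cur]]
            safe = np.minimum(vals, child_map.shape[1] - 1)
            nxt = child_map[cur, safe]
            unseen = (vals >= child_map.shape[1]) | (nxt < 0)
            out[alive[unseen]] = majority[cur[unseen]]
            alive, cur = alive[~unseen], nxt[~unseen]
        if alive.size:  # ran out of recorded levels (max_depth cut)
            out[alive] = self.levels[-1][1][cur]
        return out


def _grow_forest(
    x: np.ndarray,
    y: np.ndarray,
    roots: np.ndarray | None = None,
    n_roots: int = 1,
    max_depth: int | None = None,
) -> DecisionForest:
    """Grow gain-ratio trees level-wise, scoring all open leaves at once.

    Each categorical factor is used at most once per root-to-leaf path; a
    node splits while it is impure and some unused factor still takes more
    than one value there, choosing the highest gain ratio (ties to the
    lowest factor index) — so an impure node splits even at zero gain.
    """
    n, n_factors = x.shape
    n_levels = int(x.max()) + 1 if n else 1
    y = np.asarray(y, dtype=np.intp)
    leaf_of = np.zeros(n, dtype=np.intp) if roots is None else roots.astype(np.intp)
    n_leaves = n_roots
    used = np.zeros((n_roots, n_factors), dtype=bool)
    factor_range = np.arange(n_factors) * (n_levels * 2)
    stride = n_factors * n_levels * 2
    levels: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    depth = 0
    while True:
        flat = leaf_of[:, None] * stride + factor_range + x * 2 + y[:, None]
        counts = np.bincount(
            flat.ravel(), minlength=n_leaves * stride
        ).reshape(n_leaves, n_factors, n_levels, 2)
        nv = counts.sum(axis=3)                      # (L, F, V) per-value sizes
        cc = counts[:, 0].sum(axis=1)                # (L, 2) class counts
        node_n = cc.sum(axis=1)
        majority = np.where(2 * cc[:, CASE] > node_n, CASE, CONTROL).astype(np.int8)
        impure = (cc > 0).all(axis=1)
        candidate = (~used) & ((nv > 0).sum(axis=2) >= 2)
        splittable = impure & candidate.any(axis=1)
        if max_depth is not None and depth >= max_depth:
            splittable[:] = False
        if not splittable.any():
            levels.append(
                (np.full(n_leaves, -1, dtype=np.intp), majority,
                 np.full((n_leaves, 1), -1, dtype=np.intp))
            )
            break
        # gain ratio from x*log2(x) sums; all terms share the 1/n factor
        sum_cvy = _xlogx(counts).sum(axis=(2, 3))    # (L, F)
        sum_nv = _xlogx(nv).sum(axis=2)              # (L, F)
        sum_cy = _xlogx(cc).sum(axis=1)              # (L,)
        n_log_n = _xlogx(node_n)                     # (L,)
        gain = n_log_n[:, None] - sum_cy[:, None] - sum_nv + sum_cvy
        split_info = n_log_n[:, None] - sum_nv
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(candidate, gain / split_info, -np.inf)
        chosen = ratio.argmax(axis=1)                # first max -> lowest index
        factor = np.where(splittable, chosen, -1).astype(np.intp)
        # children: one per observed value of each split node's chosen factor
        present = nv[np.arange(n_leaves), chosen] > 0       # (L, V)
        present &= splittable[:, None]
        parent_of, value_of = np.nonzero(present)
        child_map = np.full((n_leaves, n_levels), -1, dtype=np.intp)
        child_map[parent_of, value_of] = np.arange(parent_of.size)
        levels.append((factor, majority, child_map))
        if parent_of.size == 0:
            break
        used = used[parent_of]
        used[np.arange(parent_of.size), chosen[parent_of]] = True
        # move samples of split leaves down to their child nodes
        idx = np.nonzero(splittable[leaf_of])[0]
        vals = x[idx, chosen[leaf_of[idx]]]
        leaf_of = child_map[leaf_of[idx], vals]
        x, y = x[idx], y[idx]
        n_leaves = parent_of.size
        depth += 1
    return DecisionForest(levels, n_roots)


# ---------------------------------------------------------------------------
# k-nearest neighbour (overlap distance)


def _onehot_stack(a: np.ndarray, n_levels: int) -> np.ndarray:
    """(V, rows, F) float32 indicator stack over category values."""
    return np.stack([(a == v) for v in range(n_levels)]).astype(np.float32)


def hamming_matrix(test: np.ndarray, train: np.ndarray) -> np.ndarray:
    """Pairwise overlap (Hamming) distances via per-level inner products."""
    n_levels = int(max(test.max(initial=0), train.max(initial=0))) + 1
    a = _onehot_stack(test, n_levels)
    b = _onehot_stack(train, n_levels)
    matches = np.zeros((test.shape[0], train.shape[0]), dtype=np.float32)
    for v in range(n_levels):
        matches += a[v] @ b[v].T
    return (test.shape[1] - matches).astype(np.int32)


def knn_neighbor_order(test: np.ndarray, train: np.ndarray) -> np.ndarray:
    """Training-row indices sorted by (Hamming distance, row index) per test row."""
    dist = hamming_matrix(test, train)
    return np.argsort(dist, axis=1, kind="stable")


def knn_topk(dist: np.ndarray, k_max: int) -> np.ndarray:
    """Indices of the k_max nearest training rows, ordered by (distance, row)."""
    n_train = dist.shape[1]
    k_max = min(k_max, n_train)
    shift = max(n_train.bit_length(), 1)
    key = (dist.astype(np.int32) << shift) + np.arange(n_train, dtype=np.int32)
    if k_max < n_train:
        part = np.argpartition(key, k_max - 1, axis=1)[:, :k_max]
    else:
        part = np.broadcast_to(np.arange(n_train), dist.shape).copy()
    sub = np.take_along_axis(key, part, axis=1)
    return np.take_along_axis(part, np.argsort(sub, axis=1), axis=1)


def knn_vote(
    order: np.ndarray, train_labels: np.ndarray, k: int, prior_label: int
) -> np.ndarray:
    k = min(k, order.shape[1])
    votes = train_labels[order[:, :k]].sum(axis=1)
    out = np.where(2 * votes > k, CASE, CONTROL).astype(np.int8)
    out[2 * votes == k] = prior_label
    return out


# ---------------------------------------------------------------------------
# KStar-style entropic instance learner (categorical attributes)
#
# Transformation probability from training row a to test row b:
#   prod over factors of [(1-blend) + blend*pi(b_f)] if a_f == b_f
#                        else blend*pi(b_f)
# with pi the Laplace-smoothed training frequency of the test value.  A class
# score is the mean transformation probability over that class's instances.


def _kstar_level_probs(
    x: np.ndarray, n_levels: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per factor: Laplace-smoothed level frequencies plus the unseen-value mass.

    Returns (probs (F, V), unseen (F,)); a level never observed in training
    carries the same smoothed mass as the unseen pseudo-level.
    """
    n, n_factors = x.shape
    if n_levels is None:
        n_levels = int(x.max(initial=0)) + 1
    flat = np.arange(n_factors) * n_levels + x
    counts = np.bincount(flat.ravel(), minlength=n_factors * n_levels).reshape(
        n_factors, n_levels
    )
    d = (counts > 0).sum(axis=1) + 1  # one pseudo-level for unseen values
    denom = (n + d).astype(float)
    return (counts + 1.0) / denom[:, None], 1.0 / denom


def _kstar_pi(
    level_probs: tuple[np.ndarray, np.ndarray], test: np.ndarray
) -> np.ndarray:
    """pi(b_f) for each test cell, shape (n_test, n_factors)."""
    probs, unseen = level_probs
    n_levels = probs.shape[1]
    safe = np.minimum(test, n_levels - 1)
    pi = probs[np.arange(test.shape[1]), safe]
    return np.where(test < n_levels, pi, unseen[None, :])


def _kstar_scores(
    a: np.ndarray,
    b: np.ndarray,
    test: np.ndarray,
    train_labels: np.ndarray,
    level_probs: tuple[np.ndarray, np.ndarray],
    blend: float,
    prior_label: int,
) -> np.ndarray:
    """Predictions from precomputed one-hot stacks a (test) and b (train)."""
    pi = _kstar_pi(level_probs, test)                       # (T, F)
    mismatch = np.log(blend * pi)                           # log prob when a_f != b_f
    bonus = np.log((1 - blend) + blend * pi) - mismatch     # added when a_f == b_f
    base = mismatch.sum(axis=1)                             # (T,)
    logw = np.zeros((test.shape[0], train_labels.size), dtype=np.float32)
    bonus32 = bonus.astype(np.float32)
    for v in range(a.shape[0]):
        logw += (a[v] * bonus32) @ b[v].T
    logw += base[:, None].astype(np.float32)
    w = np.exp(logw - logw.max(axis=1, keepdims=True))
    case_mask = train_labels == CASE
    n_case = case_mask.sum()
    n_control = train_labels.size - n_case
    score_case = w[:, case_mask].sum(axis=1) / n_case
    score_control = w[:, ~case_mask].sum(axis=1) / n_control
    out = np.where(score_case > score_control, CASE, CONTROL).astype(np.int8)
    out[score_case == score_control] = prior_label
    return out


def _kstar_predict(
    test: np.ndarray,
    train: np.ndarray,
    train_labels: np.ndarray,
    level_probs: tuple[np.ndarray, np.ndarray],
    blend: float,
    prior_label: int,
) -> np.ndarray:
    n_levels = int(max(test.max(initial=0), train.max(initial=0))) + 1
    a = _onehot_stack(test, n_levels)
    b = _onehot_stack(train, n_levels)
    return _kstar_scores(a, b, test, train_labels, level_probs, blend, prior_label)


def fold_instance_predictions(
    x_te: np.ndarray,
    x_tr: np.ndarray,
    y_tr: np.ndarray,
    knn_items: list[tuple[int, int]],
    kstar_items: list[tuple[int, float]],
    prior_label: int,
) -> dict[int, np.ndarray]:
    """Predictions of all kNN and KStar members of one CV fold at once.

    ``knn_items``/``kstar_items`` carry (output slot, k or blend).  The
    per-level one-hot inner products are shared between the overlap-distance
    matrix and the KStar transformation sums.
    """
    n_levels = int(max(x_te.max(initial=0), x_tr.max(initial=0))) + 1
    a = _onehot_stack(x_te, n_levels)
    b = _onehot_stack(x_tr, n_levels)
    out: dict[int, np.ndarray] = {}
    if knn_items:
        matches = np.zeros((x_te.shape[0], x_tr.shape[0]), dtype=np.float32)
        for v in range(n_levels):
            matches += a[v] @ b[v].T
        dist = (x_te.shape[1] - matches).astype(np.int32)
        top = knn_topk(dist, max(k for _, k in knn_items))
        for slot, k in knn_items:
            out[slot] = knn_vote(top, y_tr, k, prior_label)
    if kstar_items:
        level_probs = _kstar_level_probs(x_tr, n_levels)
        for slot, blend in kstar_items:
            out[slot] = _kstar_scores(a, b, x_te, y_tr, level_probs, blend, prior_label)
    return out
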