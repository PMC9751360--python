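"""Combined biomarker model of immunotherapy benefit.

Four binary features — HLA-LOH presence (grade other than negative),
TMB-high (cohort-specific cutoff, supplied by the caller), PD-L1-high
(tumor proportion score strictly above 1%) and CD8-high (at or above the
cohort median) — feed a small CART decision tree predicting durable
clinical benefit (DCB) versus no durable benefit (NDB). Model quality is
measured by the F1 score of pooled leave-one-out predictions, with tree
depth selected over 3..20 by highest LOO F1 (smallest depth on ties).

The tree is implemented here rather than delegated, because its
determinism contract is strict: greedy Gini splits, feature ties broken by
the fixed order (loh_present, tmb_high, pdl1_high, cd8_high), leaf ties
predicting NDB. Entropy is available as an alternative impurity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .io_formats import CohortRecord

FEATURE_ORDER = ("loh_present", "tmb_high", "pdl1_high", "cd8_high")
POSITIVE_CLASS = "DCB"
NEGATIVE_CLASS = "NDB"


@dataclass(frozen=True)
class FeatureVector:
    patient_id: str
    loh_present: bool
    tmb_high: bool
    pdl1_high: bool
    cd8_high: bool
    label: str | None = None

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FEATURE_ORDER], dtype=bool)


def classify_pdl1_tps(tps_percent: float) -> str:
    """Three-tier PD-L1 grading: negative (<1%), intermediate ([1%, 50%)),
    high (>=50%)."""
    if not (0.0 <= tps_percent <= 100.0):
        raise ValueError(f"TPS must lie in [0, 100], got {tps_percent}")
    if tps_percent < 1.0:
        return "negative"
    if tps_percent < 50.0:
        return "intermediate"
    return "high"


def binarize_features(
    records: Sequence[CohortRecord], tmb_cut: float
) -> list[FeatureVector]:
    """Binarize the four biomarkers over a cohort.

    pdl1_high iff TPS strictly above 1%; cd8_high iff at or above the cohort
    median CD8 level (median computed once over the full cohort); tmb_high
    iff TMB >= ``tmb_cut``; loh_present iff grade is not negative.
    """
    if not records:
        raise ValueError("empty cohort")
    cd8_median = float(np.median([r.cd8_level for r in records]))
    return [
        FeatureVector(
            patient_id=r.patient_id,
            loh_present=r.loh_grade != "negative",
            tmb_high=r.tmb >= tmb_cut,
            pdl1_high=r.pdl1_tps > 1.0,
            cd8_high=r.cd8_level >= cd8_median,
            label=r.response,
        )
        for r in records
    ]


# ---------------------------------------------------------------------------
# CART on boolean features
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """One node of the fitted tree; leaves carry a prediction and counts."""

    prediction: str
    n_dcb: int
    n_ndb: int
    split_feature: int | None = None
    left: "TreeNode | None" = None   # feature == False branch
    right: "TreeNode | None" = None  # feature == True branch

    @property
    def is_leaf(self) -> bool:
        return self.split_feature is None

    def to_dict(self) -> dict:
        out: dict = {"prediction": self.prediction,
                     "counts": {"DCB": self.n_dcb, "NDB": self.n_ndb}}
        if not self.is_leaf:
            out["split_feature"] = FEATURE_ORDER[self.split_feature]
            out["left"] = self.left.to_dict()
            out["right"] = self.right.to_dict()
        return out


@dataclass
class TreeModel:
    root: TreeNode
    max_depth: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=bool)
        if X.ndim == 1:
            X = X[None, :]
        out = []
        for row in X:
            node = self.root
            while not node.is_leaf:
                node = node.right if row[node.split_feature] else node.left
            out.append(node.prediction)
        return np.array(out)

    def depth(self) -> int:
        def _d(node: TreeNode) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(_d(node.left), _d(node.right))
        return _d(self.root)

    def to_dict(self) -> dict:
        return {"max_depth": self.max_depth, "root": self.root.to_dict()}


def _impurity(n_pos: int, n_neg: int, criterion: str) -> float:
    n = n_pos + n_neg
    if n == 0:
        return 0.0
    p = n_pos / n
    if criterion == "gini":
        return 2.0 * p * (1.0 - p)
    if p in (0.0, 1.0):
        return 0.0
    return -(p * np.log2(p) + (1 - p) * np.log2(1 - p))


def _majority(n_dcb: int, n_ndb: int) -> str:
    # tie -> NDB (conservative: do not predict benefit on ambiguous evidence)
    return POSITIVE_CLASS if n_dcb > n_ndb else NEGATIVE_CLASS


def _grow(
    X: np.ndarray, y: np.ndarray, depth_left: int, criterion: str
) -> TreeNode:
    n_dcb = int(np.sum(y == POSITIVE_CLASS))
    n_ndb = int(len(y) - n_dcb)
    node = TreeNode(prediction=_majority(n_dcb, n_ndb), n_dcb=n_dcb, n_ndb=n_ndb)
    if depth_left == 0 or n_dcb == 0 or n_ndb == 0:
        return node
    parent_imp = _impurity(n_dcb, n_ndb, criterion)
    best_gain, best_j = 0.0, None
    n = len(y)
    for j in range(X.shape[1]):
        mask = X[:, j]
        n_r = int(mask.sum())
        if n_r == 0 or n_r == n:
            continue
        r_dcb = int(np.sum(y[mask] == POSITIVE_CLASS))
        l_dcb = n_dcb - r_dcb
        child_imp = (
            (n - n_r) * _impurity(l_dcb, (n - n_r) - l_dcb, criterion)
            + n_r * _impurity(r_dcb, n_r - r_dcb, criterion)
        ) / n
        gain = parent_imp - child_imp
        # strict inequality keeps the smallest feature index on ties
        if gain > best_gain + 1e-12:
            best_gain, best_j = gain, j
    if best_j is None:
        # No single split reduces impurity, but a zero-gain split can still
        # enable a perfect split below (XOR-like labelings); take the
        # smallest-index feature that varies in the node. Leaves are only
        # forced when every feature is constant.
        for j in range(X.shape[1]):
            n_r = int(X[:, j].sum())
            if 0 < n_r < n:
                best_j = j
                break
    if best_j is None:
        return node
    mask = X[:, best_j]
    node.split_feature = best_j
    node.left = _grow(X[~mask], y[~mask], depth_left - 1, criterion)
    node.right = _grow(X[mask], y[mask], depth_left - 1, criterion)
    return node


def fit_decision_tree(
    features: np.ndarray | Sequence[FeatureVector],
    labels: Sequence[str] | None = None,
    max_depth: int = 3,
    criterion: Literal["gini", "entropy"] = "gini",
) -> TreeModel:
    """Greedy binary CART on the four boolean biomarker features.

    ``features`` may be a boolean matrix with columns in :data:`FEATURE_ORDER`
    plus ``labels``, or a sequence of labelled :class:`FeatureVector`.
    Splitting stops at ``max_depth``, node purity, or when every feature is
    constant within the node; a zero-gain split on a varying feature is
    taken when no split reduces impurity, so any labeling that is a
    deterministic function of the features is fit exactly once depth
    permits.
    """
    X, y = _as_xy(features, labels)
    if len(y) == 0:
        raise ValueError("cannot fit a tree on zero samples")
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    return TreeModel(root=_grow(X, y, max_depth, criterion), max_depth=max_depth)


def _as_xy(
    features: np.ndarray | Sequence[FeatureVector], labels: Sequence[str] | None
) -> tuple[np.ndarray, np.ndarray]:
    if labels is None:
        fvs = list(features)
        if any(fv.label is None for fv in fvs):
            raise ValueError("all feature vectors must carry a response label")
        X = np.array([fv.as_array() for fv in fvs], dtype=bool)
        y = np.array([fv.label for fv in fvs])
    else:
        X = np.asarray(features, dtype=bool)
        y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("features and labels have mismatched shapes")
    bad = set(y) - {POSITIVE_CLASS, NEGATIVE_CLASS}
    if bad:
        raise ValueError(f"unknown labels {sorted(bad)}")
    return X, y


def f1_score_pooled(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """F1 with DCB positive. No predicted positives: 1 if there are also no
    true positives, else 0."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    pred_pos = y_pred == POSITIVE_CLASS
    true_pos = y_true == POSITIVE_CLASS
    if not pred_pos.any():
        return 1.0 if not true_pos.any() else 0.0
    tp = int(np.sum(pred_pos & true_pos))
    if tp == 0:
        return 0.0
    precision = tp / pred_pos.sum()
    recall = tp / true_pos.sum() if true_pos.any() else 0.0
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def loo_f1(
    features: np.ndarray | Sequence[FeatureVector],
    labels: Sequence[str] | None = None,
    max_depth: int = 3,
    criterion: Literal["gini", "entropy"] = "gini",
) -> float:
    """Leave-one-out F1: refit on each n-1 subset, predict the held-out
    patient, pool the n predictions."""
    X, y = _as_xy(features, labels)
    n = len(y)
    if n < 2:
        raise ValueError("leave-one-out needs at least 2 samples")
    preds = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = fit_decision_tree(X[mask], y[mask], max_depth, criterion)
        preds.append(model.predict(X[i])[0])
    return f1_score_pooled(y, np.array(preds))


@dataclass(frozen=True)
class DepthSearchResult:
    per_depth_f1: dict[int, float]
    best_depth: int
    best_f1: float


def select_tree_depth(
    features: np.ndarray | Sequence[FeatureVector],
    labels: Sequence[str] | None = None,
    depths: Sequence[int] = tuple(range(3, 21)),
    criterion: Literal["gini", "entropy"] = "gini",
) -> DepthSearchResult:
    """LOO F1 per tree depth; best depth is the smallest one attaining the
    maximum F1."""
    per_depth = {d: loo_f1(features, labels, max_depth=d, criterion=criterion)
                 for d in depths}
    best_f1 = max(per_depth.values())
    best_depth = min(d for d, f in per_depth.items() if f == best_f1)
    return DepthSearchResult(per_depth_f1=per_depth, best_depth=best_depth,
                             best_f1=best_f1)


def roc_auc(scores: Sequence[float], labels: Sequence) -> float:
    """AUC as P(score_pos > score_neg) + 0.5 P(tie), via the rank-sum
    (Mann-Whitney) identity. Labels may be 0/1 or NDB/DCB."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "UO":
        pos = labels == POSITIVE_CLASS
    else:
        pos = labels.astype(bool)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
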