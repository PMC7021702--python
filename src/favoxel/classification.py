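"""Fisher-score voxel selection, linear SVM and leave-one-out CV.

The two-class Fisher score of voxel j is

    F_j = (mu_1j - mu_2j)^2 / (s2_1j + s2_2j)

with per-class means mu and unbiased (n-1) variances s2.  Voxel selection
keeps voxels with F_j strictly above a threshold, optionally restricted to
voxels whose *training* class means indicate an FA decrease (or increase)
in the positive class relative to the negative class.  Both selection and
the linear soft-margin SVM (C = 1) are recomputed inside every
leave-one-subject-out fold, so no quantity derived from the held-out
subject ever enters feature selection or training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from sklearn.svm import SVC

from favoxel.roi_features import FeatureMatrix
from favoxel.volume_io import ScalarVolume, VolumeGrid

logger = logging.getLogger(__name__)

#: fixed SVM solver tolerance for reproducible folds
SVM_TOL = 1e-6


@dataclass
class FisherScores:
    """Per-voxel Fisher scores with the class means/variances retained."""

    scores: np.ndarray  # (n_voxels,), >= 0; +inf where only the means differ
    means: np.ndarray  # (2, n_voxels) class means, row order = class_pair
    variances: np.ndarray  # (2, n_voxels) unbiased class variances
    class_pair: tuple[str, str]


@dataclass(frozen=True)
class SelectionRule:
    """Voxel-selection settings: Fisher threshold and FA-direction filter.

    ``direction`` is interpreted on the ordered ``class_pair``
    (positive, negative): "decrease" keeps voxels whose training mean FA is
    lower in the positive class (e.g. lower in AD than in controls).
    """

    fisher_threshold: float | None = None
    direction: str = "any"  # any | decrease | increase
    class_pair: tuple[str, str] = ("AD", "CTRL")

    def __post_init__(self):
        if self.fisher_threshold is not None and self.fisher_threshold < 0:
            raise ValueError("fisher_threshold must be >= 0")
        if self.direction not in ("any", "decrease", "increase"):
            raise ValueError("direction must be one of any/decrease/increase")


@dataclass
class FoldRecord:
    held_out_id: str
    true_label: str
    predicted_label: str
    n_selected: int
    selected: np.ndarray  # voxel column indices used in this fold
    fallback_used: bool = False
    decision_coef: np.ndarray | None = None  # w over the selected voxels
    decision_intercept: float | None = None


@dataclass
class CVResult:
    """Leave-one-out cross-validation outcome for one binary contrast."""

    folds: list[FoldRecord]
    class_pair: tuple[str, str]

    @property
    def n(self) -> int:
        return len(self.folds)

    @property
    def accuracy(self) -> float:
        correct = sum(f.true_label == f.predicted_label for f in self.folds)
        return correct / len(self.folds)

    def confusion(self) -> dict[str, int]:
        pos, neg = self.class_pair
        c = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
        for f in self.folds:
            if f.true_label == pos:
                c["tp" if f.predicted_label == pos else "fn"] += 1
            else:
                c["tn" if f.predicted_label == neg else "fp"] += 1
        return c

    def to_dict(self) -> dict:
        return {
            "class_pair": list(self.class_pair),
            "accuracy": self.accuracy,
            "n": self.n,
            "confusion": self.confusion(),
            "folds": [
                {
                    "held_out": f.held_out_id,
                    "true": f.true_label,
                    "predicted": f.predicted_label,
                    "n_selected": f.n_selected,
                    "fallback": f.fallback_used,
                }
                for f in self.folds
            ],
        }


@dataclass
class SweepResult:
    """LOOCV accuracy as a function of the Fisher threshold."""

    thresholds: np.ndarray
    results: list[CVResult]

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([r.accuracy for r in self.results])

    @property
    def argmax_threshold(self) -> float:
        # ties -> smallest threshold
        return float(self.thresholds[int(np.argmax(self.accuracies))])

    @property
    def best_accuracy(self) -> float:
        return float(self.accuracies.max())

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds.tolist(),
            "accuracies": self.accuracies.tolist(),
            "argmax_threshold": self.argmax_threshold,
            "best_accuracy": self.best_accuracy,
        }


def _two_class_split(X: np.ndarray, y: np.ndarray, class_pair):
    pos, neg = class_pair
    present = set(y.tolist())
    if present != {pos, neg}:
        raise ValueError(
            f"exactly the two classes {class_pair} must be present, got {sorted(present)}"
        )
    return X[y == pos], X[y == neg]


def fisher_score(
    X: np.ndarray, y: np.ndarray, class_pair: tuple[str, str]
) -> FisherScores:
    """Two-class Fisher score per voxel (column) of X.

    Degenerate voxels where both class variances vanish score +inf if the
    means differ (always selected) and 0 if they agree.
    """
    y = np.asarray(y)
    Xp, Xn = _two_class_split(np.asarray(X, dtype=float), y, class_pair)
    if len(Xp) < 2 or len(Xn) < 2:
        raise ValueError("each class needs >= 2 subjects for Fisher scoring")
    means = np.vstack([Xp.mean(axis=0), Xn.mean(axis=0)])
    variances = np.vstack([Xp.var(axis=0, ddof=1), Xn.var(axis=0, ddof=1)])
    num = (means[0] - means[1]) ** 2
    den = variances.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = num / den
    degenerate = den == 0
    scores[degenerate & (num > 0)] = np.inf
    scores[degenerate & (num == 0)] = 0.0
    return FisherScores(scores, means, variances, tuple(class_pair))


def direction_sign(
    X: np.ndarray, y: np.ndarray, class_pair: tuple[str, str]
) -> np.ndarray:
    """Per-voxel sign of (mean of negative class - mean of positive class).

    Positive sign means the positive class (listed first, e.g. AD) has the
    lower training-mean FA — an FA decrease.  Zero (tied means) belongs to
    neither direction subset.
    """
    Xp, Xn = _two_class_split(np.asarray(X, dtype=float), np.asarray(y), class_pair)
    return np.sign(Xn.mean(axis=0) - Xp.mean(axis=0))


def select_voxels(
    scores: FisherScores, rule: SelectionRule, signs: np.ndarray | None = None
) -> np.ndarray:
    """Indices of voxels passing the rule: F strictly above the threshold,
    intersected with the direction constraint when one is set."""
    keep = np.ones(scores.scores.shape, dtype=bool)
    if rule.fisher_threshold is not None:
        keep &= scores.scores > rule.fisher_threshold
    if rule.direction != "any":
        if signs is None:
            raise ValueError("direction restriction requires per-voxel signs")
        keep &= signs > 0 if rule.direction == "decrease" else signs < 0
    return np.flatnonzero(keep)


class LinearDecision:
    """Trained linear decision function f(x) = w.x + b for an ordered pair.

    Predicts the positive class when f > 0; ties (f == 0, within solver
    precision exact zeros only) go to the negative class.
    """

    def __init__(self, svc: SVC, class_pair: tuple[str, str]):
        self._svc = svc
        self.class_pair = tuple(class_pair)
        self.coef_ = svc.coef_.ravel()
        self.intercept_ = float(svc.intercept_[0])

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict(self, X: np.ndarray) -> np.ndarray:
        pos, neg = self.class_pair
        f = self.decision_function(np.atleast_2d(X))
        return np.where(f > 0, pos, neg)


def train_svm(
    X: np.ndarray, y: np.ndarray, class_pair: tuple[str, str], C: float = 1.0
) -> LinearDecision:
    """Fit a linear soft-margin SVM (hinge loss, penalty C) on the ordered
    class pair; deterministic for fixed input (fixed solver tolerance)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("training features must be 2-D with >= 1 feature")
    pos, neg = class_pair
    present = set(y.tolist())
    if present != {pos, neg}:
        raise ValueError(f"both classes of {class_pair} must be present for training")
    ynum = np.where(y == pos, 1, -1)
    svc = SVC(kernel="linear", C=C, tol=SVM_TOL)
    svc.fit(X, ynum)
    # sklearn orients the decision function so classes_[1] (+1 = pos) is positive
    return LinearDecision(svc, class_pair)


def loocv(
    features: FeatureMatrix,
    rule: SelectionRule,
    C: float = 1.0,
    leave_one_pair_out: bool = True,
) -> CVResult:
    """Leave-one-out CV with selection nested inside each training fold.

    Per fold: Fisher scores, direction signs and the selected voxel set are
    computed from the training subjects only; a linear SVM (C = 1) is
    trained on their selected voxels and predicts the held-out subject(s).
    An empty selection falls back to all voxels for that fold (logged).

    The default fold structure holds out one subject of *each* class per
    fold (k folds for k subjects per class), keeping every training set
    class-balanced; with single-subject folds (``leave_one_pair_out=False``)
    the training sets are 14-vs-15 imbalanced and a weak-signal SVM then
    drifts toward the majority class, pushing null accuracy well below
    chance.  Both modes yield exactly one prediction per subject.

    A fold whose voxel selection comes up empty has no feature basis: its
    held-out subjects get the rule's negative-class default (the f = 0 tie
    convention), which scores at chance for balanced folds.
    """
    pos, neg = rule.class_pair
    fm = features.subset_groups([pos, neg])
    y = np.asarray(fm.groups)
    X = fm.values
    for cls in (pos, neg):
        if (y == cls).sum() < 2:
            raise ValueError(f"class {cls!r} needs >= 2 subjects for LOOCV")

    if leave_one_pair_out:
        pos_idx = np.flatnonzero(y == pos)
        neg_idx = np.flatnonzero(y == neg)
        if len(pos_idx) != len(neg_idx):
            raise ValueError("leave-one-pair-out requires balanced classes")
        fold_sets = [np.array([p, q]) for p, q in zip(pos_idx, neg_idx)]
    else:
        fold_sets = [np.array([i]) for i in range(len(y))]

    folds = []
    for held in fold_sets:
        train = np.setdiff1d(np.arange(len(y)), held)
        Xtr, ytr = X[train], y[train]
        scores = fisher_score(Xtr, ytr, rule.class_pair)
        signs = direction_sign(Xtr, ytr, rule.class_pair)
        selected = select_voxels(scores, rule, signs)
        fallback = selected.size == 0
        if fallback:
            logger.debug(
                "empty voxel selection in fold holding out %s; predicting the "
                "negative class by default",
                [fm.subject_ids[i] for i in held],
            )
            preds = np.full(len(held), neg, dtype=object)
            coef, intercept = None, None
        else:
            model = train_svm(Xtr[:, selected], ytr, rule.class_pair, C=C)
            preds = model.predict(X[np.ix_(held, selected)])
            coef, intercept = model.coef_.copy(), model.intercept_
        for i, pred in zip(held, preds):
            folds.append(
                FoldRecord(
                    held_out_id=fm.subject_ids[i],
                    true_label=str(y[i]),
                    predicted_label=str(pred),
                    n_selected=int(selected.size),
                    selected=selected,
                    fallback_used=fallback,
                    decision_coef=coef,
                    decision_intercept=intercept,
                )
            )
    return CVResult(folds, rule.class_pair)


DEFAULT_THRESHOLD_GRID = np.round(np.arange(0.0, 2.0 + 1e-9, 0.1), 10)


def threshold_sweep(
    features: FeatureMatrix,
    rule: SelectionRule,
    thresholds: np.ndarray = DEFAULT_THRESHOLD_GRID,
    C: float = 1.0,
) -> SweepResult:
    """LOOCV accuracy at each Fisher threshold of an increasing grid.

    The rule's direction restriction composes conjunctively with each
    threshold.  The argmax (ties to the smallest threshold) is descriptive:
    selecting a threshold by test accuracy is optimistically biased.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("thresholds grid must be nonempty")
    results = [
        loocv(features, replace(rule, fisher_threshold=float(t)), C=C)
        for t in thresholds
    ]
    return SweepResult(thresholds, results)


CONTRASTS = (("AD", "CTRL"), ("AD", "MCI"), ("MCI", "CTRL"))


def pairwise_contrasts(
    features: FeatureMatrix, rule: SelectionRule, C: float = 1.0
) -> dict[tuple[str, str], CVResult]:
    """All three binary contrasts of a three-group cohort, each LOOCV'd
    independently on its own two-group subset."""
    groups = set(features.groups)
    if groups != {"AD", "MCI", "CTRL"}:
        raise ValueError(f"need the three groups AD/MCI/CTRL, got {sorted(groups)}")
    out = {}
    for pair in CONTRASTS:
        out[pair] = loocv(features, replace(rule, class_pair=pair), C=C)
    return out


def discriminative_map(
    features: FeatureMatrix,
    grid: VolumeGrid,
    class_pair: tuple[str, str],
    threshold: float,
) -> tuple[ScalarVolume, ScalarVolume]:
    """Descriptive Fisher-score map on all subjects of the pair, plus the
    supra-threshold mask.  For reporting only — never feeds back into CV."""
    fm = features.subset_groups(list(class_pair))
    scores = fisher_score(fm.values, np.asarray(fm.groups), class_pair)
    score_vol = np.zeros(grid.shape)
    mask_vol = np.zeros(grid.shape, dtype=np.int32)
    coords = tuple(fm.voxel_index.T)
    finite = np.where(np.isfinite(scores.scores), scores.scores, 0.0)
    score_vol[coords] = finite
    mask_vol[coords] = (scores.scores > threshold).astype(np.int32)
    return ScalarVolume(grid, score_vol), ScalarVolume(grid, mask_vol)
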