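"""Phase classifiers: ID3-style decision tree, SVM with error-correcting
output codes, and multi-class AdaBoost over decision stumps.

All three are scikit-learn compatible estimators (``fit`` / ``predict`` /
``get_params``), so they compose with sklearn pipelines and model selection.
Feature tables are z-score normalized (training statistics only) before
fitting; the trained bundle stores the normalizer, feature names and class
set so prediction is schema-checked and deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .io_config import PHASE_ORDER, PhaseLabel

logger = logging.getLogger("pcnaphase")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class Normalizer:
    """Per-feature z-score parameters estimated on training data.

    Columns with zero standard deviation map to 0 (the scaler stores unit
    scale for them and the centered value is 0).
    """

    feature_names: list[str]
    scaler: StandardScaler

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        x = table[self.feature_names].to_numpy(dtype=np.float64)
        return pd.DataFrame(self.scaler.transform(x), index=table.index,
                            columns=self.feature_names)


def fit_normalizer(table: pd.DataFrame) -> Normalizer:
    if len(table) < 2:
        raise ValueError("normalizer needs >= 2 samples")
    scaler = StandardScaler()
    scaler.fit(table.to_numpy(dtype=np.float64))
    return Normalizer(feature_names=list(table.columns), scaler=scaler)


def apply_normalizer(normalizer: Normalizer, table: pd.DataFrame) -> pd.DataFrame:
    return normalizer.transform(table)


# ---------------------------------------------------------------------------
# ID3-style decision tree
# ---------------------------------------------------------------------------

def _entropy(counts: np.ndarray) -> float:
    tot = counts.sum()
    if tot == 0:
        return 0.0
    p = counts[counts > 0] / tot
    return float(-(p * np.log2(p)).sum())


@dataclass
class _TreeNode:
    feature: int = -1
    threshold: float = 0.0
    left: "_TreeNode | None" = None
    right: "_TreeNode | None" = None
    leaf_label: int = -1

    @property
    def is_leaf(self) -> bool:
        return self.left is None


class ID3DecisionTreeClassifier(ClassifierMixin, BaseEstimator):
    """Greedy information-gain decision tree with binary threshold splits.

    Each node splits on the (feature, threshold) pair with the highest
    information gain (entropy before minus weighted entropy after);
    thresholds are midpoints between sorted distinct values (the continuous-
    attribute extension of ID3). Growth stops at purity, at ``depth_limit``,
    or when the node entropy drops below ``min_entropy``; leaves carry the
    majority class, ties resolving to the lexicographically first label.

    Parameters
    ----------
    depth_limit : int
        Maximal tree depth; 0 yields the majority-class predictor.
    min_entropy : float
        Pre-pruning: stop expanding nodes purer than this entropy [bits].
    """

    def __init__(self, depth_limit: int = 12, min_entropy: float = 0.0):
        self.depth_limit = depth_limit
        self.min_entropy = min_entropy

    @staticmethod
    def best_split(X: np.ndarray, y: np.ndarray, n_classes: int
                   ) -> tuple[int, float, float]:
        """Best (feature, threshold, information_gain) at one node; ties go
        to the lowest feature index, then the lowest threshold."""
        n = len(y)
        parent = _entropy(np.bincount(y, minlength=n_classes))
        best = (-1, 0.0, 0.0)
        for f in range(X.shape[1]):
            order = np.argsort(X[:, f], kind="stable")
            xs, ys = X[order, f], y[order]
            onehot = np.zeros((n, n_classes))
            onehot[np.arange(n), ys] = 1.0
            left_counts = np.cumsum(onehot, axis=0)          # after i+1 samples
            distinct = np.nonzero(np.diff(xs) > 0)[0]        # split after index i
            if distinct.size == 0:
                continue
            lc = left_counts[distinct]
            rc = left_counts[-1] - lc
            nl = lc.sum(axis=1)
            nr = rc.sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                def ent(counts, tot):
                    p = counts / tot[:, None]
                    t = np.where(p > 0, p * np.log2(np.maximum(p, 1e-300)), 0.0)
                    return -t.sum(axis=1)
                child = (nl * ent(lc, nl) + nr * ent(rc, nr)) / n
            gains = parent - child
            k = int(np.argmax(gains))
            if gains[k] > best[2] + 1e-12:
                thr = 0.5 * (xs[distinct[k]] + xs[distinct[k] + 1])
                best = (f, float(thr), float(gains[k]))
        return best

    def _grow(self, X: np.ndarray, y: np.ndarray, depth: int) -> _TreeNode:
        counts = np.bincount(y, minlength=len(self.classes_))
        majority = int(np.argmax(counts))  # argmax ties -> lowest class index
        node_entropy = _entropy(counts)
        if (depth >= self.depth_limit or node_entropy <= self.min_entropy
                or counts.max() == len(y)):
            return _TreeNode(leaf_label=majority)
        f, thr, gain = self.best_split(X, y, len(self.classes_))
        if f < 0 or gain <= 0:
            return _TreeNode(leaf_label=majority)
        mask = X[:, f] <= thr
        node = _TreeNode(feature=f, threshold=thr)
        node.left = self._grow(X[mask], y[mask], depth + 1)
        node.right = self._grow(X[~mask], y[~mask], depth + 1)
        return node

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        # classes sorted lexicographically: the documented tie order
        self.classes_ = np.array(sorted(np.unique(y), key=str))
        if len(self.classes_) < 2:
            logger.warning("single-class training set: degenerate tree")
        class_index = {c: i for i, c in enumerate(self.classes_)}
        yi = np.array([class_index[v] for v in y])
        self.tree_ = self._grow(X, yi, 0)
        self.n_features_in_ = X.shape[1]
        return self

    def _predict_one(self, x: np.ndarray) -> int:
        node = self.tree_
        while not node.is_leaf:
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node.leaf_label

    def predict(self, X):
        check_is_fitted(self, "tree_")
        X = check_array(X, dtype=np.float64)
        return self.classes_[[self._predict_one(x) for x in X]]

    def depth(self) -> int:
        def d(node):
            return 0 if node.is_leaf else 1 + max(d(node.left), d(node.right))
        return d(self.tree_)


# ---------------------------------------------------------------------------
# SVM + error-correcting output codes
# ---------------------------------------------------------------------------

class ECOCSVMClassifier(ClassifierMixin, BaseEstimator):
    """Soft-margin SVMs combined by an error-correcting code matrix.

    One binary SVM (objective ``1/2 ||w||^2 + C sum xi_n``) is trained per
    code-matrix column; prediction concatenates the sign bits of all columns
    and decodes to the codeword with minimal Hamming distance, ties to the
    lowest class index. The default code is one-vs-all (identity codewords):
    for each class, a distinct SVM classifies membership versus the rest.

    Parameters
    ----------
    C : float
        Slack penalty of every binary SVM.
    kernel : str
        "linear" (default) or any SVC kernel ("rbf", ...).
    code_matrix : array (n_classes, n_bits) of {0, 1}, optional
        Custom codebook; None selects one-vs-all.
    """

    def __init__(self, C: float = 1.0, kernel: str = "linear",
                 gamma: str | float = "scale", code_matrix=None):
        self.C = C
        self.kernel = kernel
        self.gamma = gamma
        self.code_matrix = code_matrix

    def fit(self, X, y):
        if self.C <= 0:
            raise ValueError("C must be > 0")
        X, y = check_X_y(X, y, dtype=np.float64)
        self.classes_ = np.array(sorted(np.unique(y), key=str))
        k = len(self.classes_)
        if k < 2:
            raise ValueError("need >= 2 classes")
        if self.code_matrix is None:
            code = np.eye(k, dtype=int)
        else:
            code = np.asarray(self.code_matrix, dtype=int)
            if code.shape[0] != k:
                raise ValueError("code matrix must have one row per class")
        self.code_ = code
        class_index = {c: i for i, c in enumerate(self.classes_)}
        yi = np.array([class_index[v] for v in y])
        self.estimators_ = []
        for bit in range(code.shape[1]):
            target = code[yi, bit]
            svm = SVC(C=self.C, kernel=self.kernel, gamma=self.gamma)
            if len(np.unique(target)) < 2:
                self.estimators_.append(("const", int(target[0])))
            else:
                self.estimators_.append(("svm", svm.fit(X, target)))
        self.n_features_in_ = X.shape[1]
        return self

    def decision_bits(self, X) -> np.ndarray:
        check_is_fitted(self, "estimators_")
        X = check_array(X, dtype=np.float64)
        bits = np.zeros((len(X), len(self.estimators_)), dtype=int)
        for b, (kind, est) in enumerate(self.estimators_):
            bits[:, b] = est if kind == "const" else est.predict(X)
        return bits

    @staticmethod
    def decode(bits: np.ndarray, code: np.ndarray) -> np.ndarray:
        """Nearest codeword by Hamming distance; ties to lowest class index."""
        dist = (bits[:, None, :] != code[None, :, :]).sum(axis=2)
        return dist.argmin(axis=1)  # argmin ties -> lowest index

    def predict(self, X):
        bits = self.decision_bits(X)
        return self.classes_[self.decode(bits, self.code_)]


# ---------------------------------------------------------------------------
# Multi-class AdaBoost over stumps
# ---------------------------------------------------------------------------

@dataclass
class _Stump:
    feature: int
    threshold: float
    left_label: int
    right_label: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(X[:, self.feature] <= self.threshold,
                        self.left_label, self.right_label)


class MulticlassAdaBoostClassifier(ClassifierMixin, BaseEstimator):
    """Stage-wise multi-class AdaBoost (SAMME weighting) over one-level
    decision trees.

    Each round fits the stump (one feature, one threshold, a class per side)
    with minimal weighted error, reweights the sample distribution, and adds
    the stump with weight ``log((1-err)/err) + log(K-1)``. Training stops
    early when the best stump is no better than chance (``err >= 1 - 1/K``),
    discarding that round. The sequence of selected features is recorded in
    ``feature_sequence_`` — boosting's implicit feature selection.
    """

    def __init__(self, rounds: int = 50):
        self.rounds = rounds

    @staticmethod
    def _fit_stump(X: np.ndarray, yi: np.ndarray, w: np.ndarray,
                   n_classes: int) -> tuple[_Stump, float]:
        best: tuple[_Stump, float] | None = None
        n = len(yi)
        for f in range(X.shape[1]):
            order = np.argsort(X[:, f], kind="stable")
            xs, ys, ws = X[order, f], yi[order], w[order]
            wk = np.zeros((n, n_classes))
            wk[np.arange(n), ys] = ws
            left = np.cumsum(wk, axis=0)
            total = left[-1]
            distinct = np.nonzero(np.diff(xs) > 0)[0]
            if distinct.size == 0:
                continue
            lc = left[distinct]            # class weight mass left of split
            rc = total[None, :] - lc
            # error = 1 - (best-left-class mass + best-right-class mass)
            err = 1.0 - (lc.max(axis=1) + rc.max(axis=1))
            k = int(np.argmin(err))
            if best is None or err[k] < best[1] - 1e-15:
                thr = 0.5 * (xs[distinct[k]] + xs[distinct[k] + 1])
                stump = _Stump(feature=f, threshold=float(thr),
                               left_label=int(lc[k].argmax()),
                               right_label=int(rc[k].argmax()))
                best = (stump, float(err[k]))
        if best is None:  # all features constant
            counts = np.bincount(yi, weights=w, minlength=n_classes)
            lab = int(counts.argmax())
            best = (_Stump(0, np.inf, lab, lab), 1.0 - counts.max() / w.sum())
        return best

    def fit(self, X, y):
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        X, y = check_X_y(X, y, dtype=np.float64)
        self.classes_ = np.array(sorted(np.unique(y), key=str))
        k = len(self.classes_)
        class_index = {c: i for i, c in enumerate(self.classes_)}
        yi = np.array([class_index[v] for v in y])
        n = len(yi)
        w = np.full(n, 1.0 / n)
        self.stumps_: list[_Stump] = []
        self.alphas_: list[float] = []
        self.feature_sequence_: list[int] = []
        chance = 1.0 - 1.0 / max(k, 2)
        for _ in range(self.rounds):
            stump, err = self._fit_stump(X, yi, w, k)
            if err >= chance:
                break  # weak learner no better than chance
            err = max(err, 1e-12)
            alpha = np.log((1.0 - err) / err) + np.log(max(k - 1, 1))
            pred = stump.predict(X)
            miss = pred != yi
            w = w * np.exp(alpha * miss)
            w /= w.sum()
            self.stumps_.append(stump)
            self.alphas_.append(float(alpha))
            self.feature_sequence_.append(stump.feature)
            if err <= 1e-12:
                break
        if not self.stumps_:
            counts = np.bincount(yi, minlength=k)
            self.stumps_.append(_Stump(0, np.inf, int(counts.argmax()),
                                       int(counts.argmax())))
            self.alphas_.append(1.0)
            self.feature_sequence_.append(0)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "stumps_")
        X = check_array(X, dtype=np.float64)
        votes = np.zeros((len(X), len(self.classes_)))
        for stump, alpha in zip(self.stumps_, self.alphas_):
            pred = stump.predict(X)
            votes[np.arange(len(X)), pred] += alpha
        return self.classes_[votes.argmax(axis=1)]


# ---------------------------------------------------------------------------
# Model bundle, training, prediction, cross-validation
# ---------------------------------------------------------------------------

CLASSIFIER_KINDS = {
    "decision_tree": ID3DecisionTreeClassifier,
    "svm": ECOCSVMClassifier,
    "adaboost": MulticlassAdaBoostClassifier,
}


@dataclass
class ClassifierModel:
    """Trained phase predictor with its embedded normalizer and schema."""

    kind: str
    estimator: BaseEstimator
    normalizer: Normalizer
    feature_names: list[str]
    classes: list[str]

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ClassifierModel":
        return joblib.load(path)


def make_estimator(kind: str, **params) -> BaseEstimator:
    if kind not in CLASSIFIER_KINDS:
        raise ValueError(f"unknown classifier kind {kind!r}")
    return CLASSIFIER_KINDS[kind](**params)


def train_model(table: pd.DataFrame, labels, kind: str = "decision_tree",
                **params) -> ClassifierModel:
    y = np.array([l.name if isinstance(l, PhaseLabel) else str(l) for l in labels])
    normalizer = fit_normalizer(table)
    x = normalizer.transform(table).to_numpy()
    est = make_estimator(kind, **params).fit(x, y)
    logger.info("train_model kind=%s n=%d p=%d classes=%s",
                kind, len(table), table.shape[1], sorted(set(y)))
    return ClassifierModel(kind=kind, estimator=est, normalizer=normalizer,
                           feature_names=list(table.columns),
                           classes=list(est.classes_))


def predict(model: ClassifierModel, table: pd.DataFrame) -> list[PhaseLabel]:
    """Schema-checked prediction: columns matched by name, any missing or
    extra feature column is an error."""
    missing = set(model.feature_names) - set(table.columns)
    extra = set(table.columns) - set(model.feature_names)
    if missing or extra:
        raise ValueError(f"feature schema mismatch: missing={sorted(missing)} "
                         f"extra={sorted(extra)}")
    x = model.normalizer.transform(table[model.feature_names]).to_numpy()
    return [PhaseLabel.parse(v) for v in model.estimator.predict(x)]


@dataclass
class CVResult:
    """k-fold cross-validation outcome: disjoint folds covering all samples."""

    k: int
    fold_confusions: list[np.ndarray]
    pooled_confusion: np.ndarray        # rows true, cols predicted
    class_order: list[str]
    accuracy: float
    seed: int


def _confusion(y_true: np.ndarray, y_pred: np.ndarray,
               class_order: list[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(class_order)}
    cm = np.zeros((len(class_order), len(class_order)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return cm


def make_folds(n: int, k: int, seed: int, y: np.ndarray | None = None,
               stratify: bool = False) -> list[np.ndarray]:
    """Seeded random partition into k disjoint folds covering all samples."""
    rng = np.random.default_rng(seed)
    if stratify and y is not None:
        folds: list[list[int]] = [[] for _ in range(k)]
        for cls in sorted(set(y), key=str):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            for j, i in enumerate(idx):
                folds[j % k].append(int(i))
        return [np.sort(np.array(f, dtype=int)) for f in folds]
    perm = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def cross_validate(table: pd.DataFrame, labels, k: int = 10,
                   kind: str = "decision_tree", seed: int = 0,
                   stratify: bool = False, **params) -> CVResult:
    """k-fold CV with per-fold refitting of both normalizer and model on the
    training part only (no leakage into the held-out fold)."""
    y = np.array([l.name if isinstance(l, PhaseLabel) else str(l) for l in labels])
    n = len(table)
    if n < k:
        raise ValueError("need at least k samples")
    class_order = sorted(set(y), key=str)
    folds = make_folds(n, k, seed, y=y, stratify=stratify)
    fold_cms = []
    for fold in folds:
        test = np.zeros(n, dtype=bool)
        test[fold] = True
        train_df = table.iloc[~test]
        if len(set(y[~test])) < len(class_order):
            logger.warning("a class is absent from a training fold")
        normalizer = fit_normalizer(train_df)
        est = make_estimator(kind, **params)
        est.fit(normalizer.transform(train_df).to_numpy(), y[~test])
        pred = est.predict(normalizer.transform(table.iloc[test]).to_numpy())
        fold_cms.append(_confusion(y[test], pred, class_order))
    pooled = np.sum(fold_cms, axis=0)
    accuracy = float(np.trace(pooled)) / float(pooled.sum())
    logger.info("cross_validate kind=%s k=%d n=%d accuracy=%.4f",
                kind, k, n, accuracy)
    return CVResult(k=k, fold_confusions=fold_cms, pooled_confusion=pooled,
                    class_order=class_order, accuracy=accuracy, seed=seed)
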