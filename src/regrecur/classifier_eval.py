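"""Random-forest training and evaluation for labeled mutation feature tables.

The classifier is a 1000-tree bagged forest of CART trees (scikit-learn
decision trees; mtry = floor(sqrt(n_features)), unlimited depth, minimum
node size 1, bootstrap with replacement — the classic randomForest
classification defaults).  Bagging is done here rather than through a
monolithic forest estimator so that each tree's bootstrap multiplicities,
and hence its exact out-of-bag (OOB) rows, are first-class: OOB rows drive
the permutation variable importance (Mean Decrease Accuracy), and per-tree
majority votes give each mutation its vote proportion.

Evaluation: 10-repeated stratified 5-fold cross-validation with per-repeat
AUC from the pooled held-out votes; leave-one-sample-out CV that rebuilds
the training false set away from the held-out sample; label randomization
as the null control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import sklearn
from scipy.stats import rankdata
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

META_COLUMNS = ("mutation_key", "sample_id", "label")
N_TREES_DEFAULT = 1000
_MAX_SEED = 2**31 - 1


def validate_feature_table(table: pd.DataFrame,
                           feature_names: Sequence[str] | None = None) -> list[str]:
    """Check the labeled feature-table schema and return the feature columns."""
    for col in META_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"feature table missing column {col!r}")
    feats = [c for c in table.columns if c not in META_COLUMNS]
    if feature_names is not None:
        missing = sorted(set(feature_names) - set(feats))
        extra = sorted(set(feats) - set(feature_names))
        if missing or extra:
            raise ValueError(f"feature schema mismatch: missing={missing}, "
                             f"extra={extra}")
        feats = list(feature_names)
    X = table[feats].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("feature table contains non-finite values")
    return feats


class RandomForest:
    """Bagged CART forest with explicit bootstrap weights and OOB masks."""

    def __init__(self, n_trees: int = N_TREES_DEFAULT,
                 mtry: int | None = None, seed: int = 0):
        self.n_trees = n_trees
        self.mtry = mtry
        self.seed = seed
        self.trees: list[DecisionTreeClassifier] = []
        self.oob: np.ndarray | None = None        # (n_trees, n_rows) bool
        self.n_features_: int | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RandomForest":
        X = np.asfortranarray(np.asarray(X, dtype=np.float32))
        y = np.asarray(y, dtype=np.float64)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training table must contain both classes")
        n = len(y)
        if n < 2:
            raise ValueError("need at least 2 training rows")
        mtry = self.mtry or max(1, int(np.sqrt(X.shape[1])))
        rs = np.random.RandomState(self.seed)
        self.trees = []
        self.oob = np.zeros((self.n_trees, n), dtype=bool)
        # parameter validation is redundant inside this tight loop
        with sklearn.config_context(assume_finite=True,
                                    skip_parameter_validation=True):
            for t in range(self.n_trees):
                idx = rs.randint(0, n, n)
                w = np.bincount(idx, minlength=n).astype(np.float64)
                tree = DecisionTreeClassifier(
                    max_features=mtry, random_state=rs.randint(_MAX_SEED))
                tree.fit(X, y, sample_weight=w, check_input=False)
                self.trees.append(tree)
                self.oob[t] = w == 0
        self.n_features_ = X.shape[1]
        return self

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(np.asarray(X, dtype=np.float32))
        if X.shape[1] != self.n_features_:
            raise ValueError(f"expected {self.n_features_} features, got {X.shape[1]}")
        return X

    def tree_predictions(self, X: np.ndarray) -> np.ndarray:
        """(n_trees, n_rows) matrix of per-tree majority-leaf class labels."""
        X = self._check_X(X)
        with sklearn.config_context(assume_finite=True,
                                    skip_parameter_validation=True):
            return np.stack([t.predict(X, check_input=False) for t in self.trees])

    def vote_proportions(self, X: np.ndarray) -> np.ndarray:
        """Per-row fraction of trees voting the positive class."""
        return self.tree_predictions(X).mean(axis=0)


@dataclass
class ForestHandle:
    """A trained forest plus the schema and rows it was trained on."""

    forest: RandomForest
    feature_names: list[str]
    train_keys: list[str]
    train_votes: np.ndarray       # vote proportions on the training rows
    oob_votes: np.ndarray         # OOB-only vote proportions (NaN if never OOB)


def train_forest(table: pd.DataFrame, n_trees: int = N_TREES_DEFAULT,
                 seed: int = 0, mtry: int | None = None) -> ForestHandle:
    """Fit the forest on a labeled feature table.

    Exposes training-row vote proportions and, separately, votes restricted
    to trees for which the row was out of bag (the honest training-set
    estimate).
    """
    feats = validate_feature_table(table)
    X = table[feats].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=bool).astype(np.float64)
    if min((y == 1).sum(), (y == 0).sum()) < 1 or len(y) < 2:
        raise ValueError("training table must contain both classes")
    rf = RandomForest(n_trees=n_trees, mtry=mtry, seed=seed).fit(X, y)
    preds = rf.tree_predictions(X)
    with np.errstate(invalid="ignore"):
        oob_votes = np.where(rf.oob.any(axis=0),
                             (preds * rf.oob).sum(axis=0)
                             / np.maximum(rf.oob.sum(axis=0), 1), np.nan)
    return ForestHandle(forest=rf, feature_names=feats,
                        train_keys=table["mutation_key"].tolist(),
                        train_votes=preds.mean(axis=0), oob_votes=oob_votes)


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """AUC via the Mann-Whitney rank statistic with midranks for ties.

    Identical to the trapezoidal area under the tie-aware ROC curve.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes")
    ranks = rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class CVReport:
    aucs: list[float]             # one per repeat
    mean_auc: float
    roc_points: tuple[np.ndarray, np.ndarray]   # pooled (FPR, TPR)


def _stratified_folds(y: np.ndarray, folds: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Fold id per row, balanced within each class."""
    assign = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if len(idx) < folds:
            raise ValueError(f"class {cls} has {len(idx)} rows < {folds} folds")
        idx = rng.permutation(idx)
        assign[idx] = np.arange(len(idx)) % folds
    return assign


def repeated_cv(table: pd.DataFrame, folds: int = 5, repeats: int = 10,
                n_trees: int = N_TREES_DEFAULT, seed: int = 0,
                mtry: int | None = None) -> CVReport:
    """Repeated stratified k-fold CV; per-repeat AUC pools the held-out votes."""
    from sklearn.metrics import roc_curve

    feats = validate_feature_table(table)
    X = table[feats].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=bool).astype(np.float64)
    rng = np.random.default_rng(seed)
    aucs = []
    all_scores: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    for rep in range(repeats):
        assign = _stratified_folds(y, folds, rng)
        scores = np.empty(len(y))
        for f in range(folds):
            test = assign == f
            rf = RandomForest(n_trees=n_trees, mtry=mtry,
                              seed=int(rng.integers(_MAX_SEED)))
            rf.fit(X[~test], y[~test])
            scores[test] = rf.vote_proportions(X[test])
        aucs.append(roc_auc(scores, y.astype(bool)))
        all_scores.append(scores)
        all_labels.append(y)
    pooled_s = np.concatenate(all_scores)
    pooled_y = np.concatenate(all_labels)
    fpr, tpr, _ = roc_curve(pooled_y, pooled_s)
    return CVReport(aucs=aucs, mean_auc=float(np.mean(aucs)),
                    roc_points=(fpr, tpr))


def randomize_labels(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Uniformly permute the label column across rows (features untouched)."""
    rng = np.random.default_rng(seed)
    out = table.copy()
    out["label"] = out["label"].to_numpy()[rng.permutation(len(out))]
    return out


@dataclass(frozen=True)
class VoteRecord:
    mutation_key: str
    sample_id: str
    vote: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.vote <= 1.0:
            raise ValueError(f"vote proportion {self.vote} outside [0, 1]")


def loocv_by_sample(table: pd.DataFrame, n_trees: int = N_TREES_DEFAULT,
                    seed: int = 0, ratio: int = 3,
                    mtry: int | None = None) -> list[VoteRecord]:
    """Leave-one-sample-out CV: hold out all rows of one sample at a time.

    The training set keeps every true row from the remaining samples and
    redraws the false rows from the remaining samples at ``ratio`` times the
    true count, so the held-out sample contributes nothing to training
    (asserted).  Returns one VoteRecord per table row.
    """
    feats = validate_feature_table(table)
    samples = sorted(table["sample_id"].unique())
    if len(samples) < 2:
        raise ValueError("LOOCV needs >= 2 distinct samples")
    rng = np.random.default_rng(seed)
    records: list[VoteRecord] = []
    for s in samples:
        held = table[table["sample_id"] == s]
        rest = table[table["sample_id"] != s]
        trues = rest[rest["label"].astype(bool)]
        falses = rest[~rest["label"].astype(bool)]
        if trues.empty or falses.empty:
            raise ValueError(f"holding out {s!r} leaves a single-class training set")
        want = min(ratio * len(trues), len(falses))
        pick = rng.choice(len(falses), size=want, replace=False)
        train = pd.concat([trues, falses.iloc[np.sort(pick)]])
        assert not (train["sample_id"] == s).any(), "held-out sample leaked into training"
        rf = RandomForest(n_trees=n_trees, mtry=mtry,
                          seed=int(rng.integers(_MAX_SEED)))
        rf.fit(train[feats].to_numpy(float),
               train["label"].to_numpy(bool).astype(np.float64))
        votes = rf.vote_proportions(held[feats].to_numpy(float))
        for (_, row), v in zip(held.iterrows(), votes):
            records.append(VoteRecord(row["mutation_key"], s, float(v)))
    return records


@dataclass
class ImportanceReport:
    mda_percent: dict[str, float]   # feature -> mean decrease accuracy (%)


def variable_importance(table: pd.DataFrame, n_trees: int = N_TREES_DEFAULT,
                        seed: int = 0,
                        mtry: int | None = None) -> ImportanceReport:
    """Permutation variable importance (Mean Decrease Accuracy, %).

    For each tree: accuracy on its out-of-bag rows minus accuracy after
    permuting one feature's values among those rows, averaged over trees and
    expressed in percentage points.  Weakly informative features can come
    out slightly negative — permutation noise, not a bug.
    """
    feats = validate_feature_table(table)
    X = np.ascontiguousarray(table[feats].to_numpy(dtype=np.float32))
    y = table["label"].to_numpy(dtype=bool).astype(np.float64)
    rf = RandomForest(n_trees=n_trees, mtry=mtry, seed=seed)
    rf.fit(X, y)
    rng = np.random.default_rng(seed + 1)
    decreases = np.zeros((len(feats), rf.n_trees))
    used = np.zeros(rf.n_trees, dtype=bool)
    with sklearn.config_context(assume_finite=True,
                                skip_parameter_validation=True):
        for t, tree in enumerate(rf.trees):
            oob = np.flatnonzero(rf.oob[t])
            if len(oob) == 0:
                continue
            used[t] = True
            Xo = X[oob]
            yo = y[oob]
            base = float((tree.predict(Xo, check_input=False) == yo).mean())
            for j in range(len(feats)):
                Xp = Xo.copy()
                Xp[:, j] = Xo[rng.permutation(len(oob)), j]
                acc = float((tree.predict(Xp, check_input=False) == yo).mean())
                decreases[j, t] = base - acc
    if not used.any():
        raise ValueError("no tree has out-of-bag rows; cannot compute MDA")
    mda = decreases[:, used].mean(axis=1) * 100.0
    return ImportanceReport(mda_percent=dict(zip(feats, mda.tolist())))


def predict_votes(handle: ForestHandle, features: pd.DataFrame) -> list[VoteRecord]:
    """Vote proportions for new rows; the feature schema must match training."""
    cols = [c for c in features.columns if c not in META_COLUMNS]
    missing = sorted(set(handle.feature_names) - set(cols))
    extra = sorted(set(cols) - set(handle.feature_names))
    if missing or extra:
        raise ValueError(f"feature schema mismatch: missing={missing}, extra={extra}")
    X = features[handle.feature_names].to_numpy(dtype=float)
    votes = handle.forest.vote_proportions(X)
    keys = (features["mutation_key"] if "mutation_key" in features.columns
            else pd.Series([str(i) for i in range(len(features))]))
    samples = (features["sample_id"] if "sample_id" in features.columns
               else pd.Series([""] * len(features)))
    return [VoteRecord(str(k), str(s), float(v))
            for k, s, v in zip(keys, samples, votes)]
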