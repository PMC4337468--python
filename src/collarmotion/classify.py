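"""Random-forest mobility and behavior models.

Two classifiers share one training recipe: 500 trees, each grown on an
independent random subsample of 1000 rows drawn *without* replacement, with
5 candidate predictors per split; a window's class is the majority vote of
the trees, ties broken at random (seeded). The mobility model is two-class
(mobile vs non-mobile); the behavior model distinguishes rest, feed, groom,
low- and high-acceleration movement. Mobility labels derive from behavior
labels: the two locomotor classes are mobile, everything else non-mobile.

The per-tree subsample-without-replacement scheme is realised with a bagging
ensemble over decision trees (``bootstrap=False``), which follows the recipe
literally; a plain random forest would bootstrap with replacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_COLUMNS, downsample, features_frame
from .trace import AccelTrace

logger = logging.getLogger(__name__)

MOBILE = "mobile"
NON_MOBILE = "non-mobile"

#: behavior -> mobility class
MOBILITY_MAP = {
    "low_move": MOBILE,
    "high_move": MOBILE,
    "rest": NON_MOBILE,
    "feed": NON_MOBILE,
    "groom": NON_MOBILE,
}

N_TREES = 500
SUBSAMPLE = 1000
MTRY = 5


def mobility_labels(behavior_labels) -> np.ndarray:
    """Map 5-class behavior labels to the 2-class mobility labels."""
    return np.asarray([MOBILITY_MAP[b] for b in np.asarray(behavior_labels)])


@dataclass
class TrainedModel:
    """A fitted forest plus everything needed for deterministic prediction."""

    task: str  # "mobility" or "behavior"
    forest: BaggingClassifier
    classes: np.ndarray
    seed: int
    n_trees: int = N_TREES
    subsample: int = SUBSAMPLE
    mtry: int = MTRY

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Majority vote over trees with a seeded random tie-break."""
        X = np.asarray(features[FEATURE_COLUMNS], dtype=float)
        classes = self.forest.classes_
        votes = np.zeros((X.shape[0], classes.size), dtype=np.int32)
        idx = np.arange(X.shape[0])
        for est in self.forest.estimators_:
            votes[idx, est.predict(X).astype(int)] += 1
        top = votes.max(axis=1, keepdims=True)
        is_top = votes == top
        rng = np.random.default_rng(self.seed + 0x7EB)  # fresh per call: deterministic
        pick = np.empty(X.shape[0], dtype=int)
        n_top = is_top.sum(axis=1)
        pick[n_top == 1] = np.argmax(is_top[n_top == 1], axis=1)
        for i in np.nonzero(n_top > 1)[0]:
            pick[i] = rng.choice(np.nonzero(is_top[i])[0])
        return classes[pick]


def train(
    features: pd.DataFrame,
    labels,
    task: str = "mobility",
    seed: int = 0,
    n_trees: int = N_TREES,
    subsample: int = SUBSAMPLE,
    mtry: int = MTRY,
) -> TrainedModel:
    """Fit a forest with the standard recipe.

    ``features`` must contain the 16 predictor columns; ``labels`` are the
    window classes (mobility labels for ``task="mobility"``). When fewer
    than ``subsample`` rows are available each tree sees all of them (logged).
    """
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"missing predictor columns: {missing}")
    y = np.asarray(labels)
    X = np.asarray(features[FEATURE_COLUMNS], dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features/labels length mismatch")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to train")
    m = min(subsample, X.shape[0])
    if m < subsample:
        logger.info("subsample clipped to n=%d (< %d requested)", m, subsample)
    forest = BaggingClassifier(
        estimator=DecisionTreeClassifier(max_features=mtry),
        n_estimators=n_trees,
        max_samples=m,
        bootstrap=False,
        random_state=seed,
        n_jobs=None,
    )
    # trees predict class indices so votes can be tallied with integer math
    y_idx = np.searchsorted(classes, y)
    forest.fit(X, y_idx)
    forest.classes_ = classes  # replace index classes with the labels
    return TrainedModel(task=task, forest=forest, classes=classes, seed=seed,
                        n_trees=n_trees, subsample=subsample, mtry=mtry)


@dataclass
class ConfusionMatrix:
    """Actual-by-predicted count table with per-class and overall accuracy."""

    table: pd.DataFrame  # rows = actual, columns = predicted
    per_class_accuracy: pd.Series = field(init=False)  # percent
    overall_accuracy: float = field(init=False)  # percent

    def __post_init__(self) -> None:
        counts = self.table.to_numpy(dtype=float)
        row_sums = counts.sum(axis=1)
        diag = np.diag(counts)
        with np.errstate(invalid="ignore", divide="ignore"):
            acc = np.where(row_sums > 0, 100.0 * diag / row_sums, np.nan)
        self.per_class_accuracy = pd.Series(acc, index=self.table.index)
        self.overall_accuracy = float(100.0 * diag.sum() / counts.sum())

    @classmethod
    def from_counts(cls, counts, labels) -> "ConfusionMatrix":
        """Build from a printed square count table (worked examples)."""
        table = pd.DataFrame(np.asarray(counts, dtype=int), index=labels, columns=labels)
        return cls(table)

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["percent_accurate"] = self.per_class_accuracy.round(1)
        return out


def evaluate(model: TrainedModel, features: pd.DataFrame, labels) -> ConfusionMatrix:
    """Confusion matrix of actual (rows) vs predicted (columns) classes."""
    y = np.asarray(labels)
    if y.shape[0] != features.shape[0]:
        raise ValueError("features/labels length mismatch")
    pred = model.predict(features)
    all_classes = np.union1d(model.classes, np.unique(y))
    table = pd.crosstab(
        pd.Categorical(y, categories=all_classes),
        pd.Categorical(pred, categories=all_classes),
        dropna=False,
    )
    table.index = pd.Index(all_classes, name="actual")
    table.columns = pd.Index(all_classes, name="predicted")
    return ConfusionMatrix(table)


def variable_importance(
    model: TrainedModel,
    features: pd.DataFrame,
    labels,
    n_permutations: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance: mean accuracy drop when a predictor is shuffled.

    Returned table has one row per predictor, sorted descending (ties stable
    in canonical column order).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    base = np.mean(model.predict(features) == y)
    drops = {}
    for col in FEATURE_COLUMNS:
        accs = []
        for _ in range(n_permutations):
            shuffled = features.copy()
            shuffled[col] = rng.permutation(shuffled[col].to_numpy())
            accs.append(np.mean(model.predict(shuffled) == y))
        drops[col] = base - float(np.mean(accs))
    out = pd.DataFrame(
        {"predictor": list(drops), "importance": list(drops.values())}
    )
    out = out.sort_values("importance", ascending=False, kind="stable").reset_index(drop=True)
    return out


def train_test_split_indices(
    labels, test_size: float = 0.3, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified split on window labels; returns (train_idx, test_idx)."""
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        idx = rng.permutation(idx)
        n_test = int(round(test_size * idx.size))
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def downsampling_experiment(
    trace: AccelTrace,
    behavior_labels,
    freqs=(64, 32, 16, 8, 4, 2),
    seed: int = 0,
    test_size: float = 0.3,
) -> pd.DataFrame:
    """Mobility-model accuracy as a function of sampling frequency.

    The 64-Hz trace is decimated to each frequency, features re-extracted,
    and a mobility forest trained and evaluated on one fixed stratified
    train/test split (windows correspond one-to-one across frequencies, so
    the split is shared).
    """
    y = mobility_labels(behavior_labels)
    train_idx, test_idx = train_test_split_indices(y, test_size, seed)
    rows = []
    for fs in freqs:
        feats = features_frame(downsample(trace, fs))
        model = train(feats.iloc[train_idx], y[train_idx], task="mobility", seed=seed)
        cm = evaluate(model, feats.iloc[test_idx], y[test_idx])
        rows.append({"fs": fs, "accuracy": cm.overall_accuracy})
    return pd.DataFrame(rows)
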