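"""Random-forest classification with repeated-split validation.

The feature table (one row per cell, six texture parameters, class
label) is split at random into training and testing subsets — 70/30 by
default, stratified by class — a random forest is trained on the
training subset only, and ROC/AUC and confusion-matrix statistics are
measured on the held-out cells.  Because a single split of a ~170-cell
cohort is noisy, the split is redrawn K = 500 times and means and
standard deviations of the metrics reported.

Overtraining is controlled with a shuffle null: the forest is trained
exactly as before, but the *test-set* labels are randomly permuted
before evaluation.  A sound pipeline then yields AUC 0.5 and ~50 %
accuracy; one-way ANOVA between the actual and null AUC samples
quantifies the significance of the separation.

The positive class throughout is "cancerous": scores are the forest's
predicted probability that a cell is cancerous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .io_qc import CANCEROUS
from .surfparams import PARAMETER_NAMES

#: Metrics summarised over repeated splits.
METRICS = ("auc", "accuracy", "sensitivity", "specificity")


@dataclass
class SplitConfig:
    """Repeated random train/test split protocol."""

    train_fraction: float = 0.7
    k_repeats: int = 500
    base_seed: int = 0
    stratified: bool = True

    def validate(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.k_repeats < 1:
            raise ValueError("k_repeats must be >= 1")


@dataclass
class ForestConfig:
    """Random-forest hyperparameters (standard defaults, all exposed)."""

    n_trees: int = 100
    max_features: str | int | float = "sqrt"
    min_leaf_size: int = 1

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class EvalResult:
    """ROC, AUC and confusion statistics of one train/test split.

    The confusion entries are class-normalized rates: ``tp + fn = 1``
    over the truly positive (cancerous) cells and ``tn + fp = 1`` over
    the truly negative ones.  ``accuracy`` uses the raw counts,
    ``(TN + TP) / (TP + FN + TN + FP)``.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    tp: float
    tn: float
    fp: float
    fn: float
    sensitivity: float
    specificity: float
    accuracy: float


@dataclass
class CVSummary:
    """Metric means/SDs over K repeated splits, plus the AUC samples."""

    mode: str  # "actual" or "shuffled_null"
    k_repeats: int
    mean: dict[str, float]
    std: dict[str, float]
    auc_samples: np.ndarray
    samples: dict[str, np.ndarray] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "k_repeats": self.k_repeats,
            "mean": {k: float(v) for k, v in self.mean.items()},
            "std": {k: float(v) for k, v in self.std.items()},
            "auc_samples": [float(a) for a in self.auc_samples],
        }


@dataclass
class SignificanceResult:
    """One-way ANOVA between actual and null AUC samples."""

    f_statistic: float
    p_value: float
    group_sizes: tuple[int, int]


def _split_seed(base_seed: int, repeat_index: int, purpose: int) -> int:
    ss = np.random.SeedSequence([base_seed, repeat_index, purpose])
    return int(ss.generate_state(1)[0] % (2**31))


def _validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in PARAMETER_NAMES if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing}")
    if "class" not in table.columns:
        raise ValueError("feature table lacks the 'class' label column")
    feats = table[list(PARAMETER_NAMES)]
    if feats.isna().any().any():
        bad = table.loc[feats.isna().any(axis=1), "cell_id"].tolist() \
            if "cell_id" in table.columns else feats.index[feats.isna().any(axis=1)].tolist()
        raise ValueError(f"feature table contains missing values (cells {bad})")
    counts = table["class"].value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 cells in each of the two classes")


# ---------------------------------------------------------------------------
# splitting


def split_train_test(
    table: pd.DataFrame, config: SplitConfig, repeat_index: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one train/test partition of the feature table.

    Stratified by class when enabled: each class contributes
    ``floor(train_fraction * n_class)`` cells to the training side and
    the remainder to testing, so both classes are always represented in
    both subsets.  Deterministic in ``(base_seed, repeat_index)``.
    """
    config.validate()
    rng = np.random.default_rng(_split_seed(config.base_seed, repeat_index, 0))
    if config.stratified:
        train_idx: list[np.ndarray] = []
        for _, group in table.groupby("class", sort=True):
            perm = group.index.to_numpy()[rng.permutation(len(group))]
            n_train = int(np.floor(config.train_fraction * len(group)))
            train_idx.append(perm[:n_train])
        train_set = np.concatenate(train_idx)
    else:
        perm = table.index.to_numpy()[rng.permutation(len(table))]
        train_set = perm[: int(np.floor(config.train_fraction * len(table)))]
    mask = table.index.isin(train_set)
    return table.loc[mask], table.loc[~mask]


# ---------------------------------------------------------------------------
# the forest


class SurfaceTextureClassifier(ClassifierMixin, BaseEstimator):
    """Random forest over the six-parameter feature vectors.

    A thin, configuration-stable wrapper around a bagged ensemble of
    decision trees with square-root feature sampling; exposes the
    probability that a cell is cancerous via ``predict_proba``.
    """

    def __init__(
        self,
        n_trees: int = 100,
        max_features: str | int | float = "sqrt",
        min_leaf_size: int = 1,
        random_state: int | None = None,
    ):
        self.n_trees = n_trees
        self.max_features = max_features
        self.min_leaf_size = min_leaf_size
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("training data contains a single class")
        if counts.min() < 2:
            raise ValueError("need >= 2 training cells per class")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=self.max_features,
            min_samples_leaf=self.min_leaf_size,
            random_state=self.random_state,
        ).fit(X, y)
        self.classes_ = self.forest_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(np.asarray(X, dtype=float))

    def cancer_probability(self, X) -> np.ndarray:
        """P(cancerous) per cell, the score used for ROC analysis."""
        proba = self.predict_proba(X)
        pos = list(self.classes_).index(CANCEROUS) \
            if CANCEROUS in self.classes_ else 1
        return proba[:, pos]


def train_forest(
    train: pd.DataFrame, config: ForestConfig, seed: int
) -> SurfaceTextureClassifier:
    """Fit the forest on the training rows of a feature table."""
    config.validate()
    clf = SurfaceTextureClassifier(
        n_trees=config.n_trees,
        max_features=config.max_features,
        min_leaf_size=config.min_leaf_size,
        random_state=seed,
    )
    return clf.fit(train[list(PARAMETER_NAMES)].to_numpy(), train["class"].to_numpy())


# ---------------------------------------------------------------------------
# ROC / confusion


def _as_binary(labels: Sequence) -> np.ndarray:
    """Map labels to {0, 1} with cancerous (or True/1) as positive."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        return (arr == CANCEROUS).astype(int)
    return arr.astype(int)


def roc_curve_points(
    scores: Sequence[float], labels: Sequence
) -> tuple[np.ndarray, np.ndarray]:
    """ROC points over the entire threshold range.

    Thresholds sweep the distinct score values from above the maximum
    (point (0, 0)) downwards to below the minimum (point (1, 1)); tied
    scores move the operating point diagonally in one step, which makes
    the trapezoid area equal to the tie-aware pair-concordance AUC.
    """
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("ROC needs at least one cell of each class")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    # keep only the last index of each tied-score run
    distinct = np.nonzero(np.diff(s_sorted))[0]
    cut = np.concatenate((distinct, [len(s_sorted) - 1]))
    tps = np.cumsum(y_sorted)[cut]
    fps = np.cumsum(1 - y_sorted)[cut]
    tpr = np.concatenate(([0.0], tps / y.sum()))
    fpr = np.concatenate(([0.0], fps / (len(y) - y.sum())))
    return fpr, tpr


def auc_trapezoid(fpr: np.ndarray, tpr: np.ndarray) -> float:
    """Area under the ROC curve by the trapezoid rule."""
    return float(np.trapezoid(tpr, fpr))


def auc_concordance(scores: Sequence[float], labels: Sequence) -> float:
    """Pair-concordance (Mann–Whitney) AUC with half credit for ties.

    Equals the trapezoid AUC of :func:`roc_curve_points` exactly; kept
    as an in-package second route for cross-checks.
    """
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("concordance needs both classes")
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)


def confusion_at_threshold(
    scores: Sequence[float], labels: Sequence, threshold: float = 0.5
) -> dict[str, float]:
    """Class-normalized confusion rates and derived metrics.

    ``tp``/``fn`` are rates over the truly cancerous cells (tp + fn = 1)
    and ``tn``/``fp`` over the truly precancerous ones (tn + fp = 1);
    sensitivity = TP/(TP + FN), specificity = TN/(TN + FP), accuracy =
    (TN + TP)/(TP + FN + TN + FP) on the raw counts.
    """
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("confusion matrix needs both classes")
    pred = (s >= threshold).astype(int)
    tp_n = int(np.sum((pred == 1) & (y == 1)))
    tn_n = int(np.sum((pred == 0) & (y == 0)))
    fp_n = n_neg - tn_n
    fn_n = n_pos - tp_n
    return {
        "tp": tp_n / n_pos,
        "fn": fn_n / n_pos,
        "tn": tn_n / n_neg,
        "fp": fp_n / n_neg,
        "sensitivity": tp_n / (tp_n + fn_n),
        "specificity": tn_n / (tn_n + fp_n),
        "accuracy": (tn_n + tp_n) / (tp_n + fn_n + tn_n + fp_n),
    }


def roc_and_auc(
    scores: Sequence[float], labels: Sequence, threshold: float = 0.5
) -> EvalResult:
    """Full evaluation of one scored test set."""
    fpr, tpr = roc_curve_points(scores, labels)
    conf = confusion_at_threshold(scores, labels, threshold)
    return EvalResult(
        fpr=fpr,
        tpr=tpr,
        auc=auc_trapezoid(fpr, tpr),
        tp=conf["tp"],
        tn=conf["tn"],
        fp=conf["fp"],
        fn=conf["fn"],
        sensitivity=conf["sensitivity"],
        specificity=conf["specificity"],
        accuracy=conf["accuracy"],
    )


# ---------------------------------------------------------------------------
# repeated splits


def _randomize_labels(
    labels: np.ndarray, rng: np.random.Generator, method: str
) -> np.ndarray:
    """Destroy the label/score association of a test set.

    ``assign`` draws every label independently and uniformly from the
    two classes (redrawing the rare all-one-class outcome), so expected
    accuracy, sensitivity and specificity are all exactly 50 %;
    ``permute`` shuffles the existing labels, preserving the class
    multiset (and hence the cohort's class imbalance) instead.
    """
    if method == "permute":
        return labels[rng.permutation(len(labels))]
    if method == "assign":
        classes = np.unique(labels)
        for _ in range(100):
            drawn = rng.choice(classes, size=len(labels))
            if len(np.unique(drawn)) == len(classes):
                return drawn
        raise RuntimeError("could not draw a two-class random assignment")
    raise ValueError(f"unknown null method {method!r}")


def _run_repeats(
    table: pd.DataFrame,
    split_config: SplitConfig,
    forest_config: ForestConfig,
    shuffle_test_labels: bool,
    null_method: str = "assign",
) -> CVSummary:
    _validate_table(table)
    split_config.validate()
    forest_config.validate()
    samples = {m: np.empty(split_config.k_repeats) for m in METRICS}
    for r in range(split_config.k_repeats):
        train, test = split_train_test(table, split_config, r)
        clf = train_forest(
            train, forest_config, seed=_split_seed(split_config.base_seed, r, 1)
        )
        scores = clf.cancer_probability(test[list(PARAMETER_NAMES)].to_numpy())
        labels = test["class"].to_numpy()
        if shuffle_test_labels:
            rng = np.random.default_rng(
                _split_seed(split_config.base_seed, r, 2)
            )
            labels = _randomize_labels(labels, rng, null_method)
        res = roc_and_auc(scores, labels)
        samples["auc"][r] = res.auc
        samples["accuracy"][r] = res.accuracy
        samples["sensitivity"][r] = res.sensitivity
        samples["specificity"][r] = res.specificity
    return CVSummary(
        mode="shuffled_null" if shuffle_test_labels else "actual",
        k_repeats=split_config.k_repeats,
        mean={m: float(np.mean(v)) for m, v in samples.items()},
        std={m: float(np.std(v, ddof=1)) for m, v in samples.items()},
        auc_samples=samples["auc"],
        samples=samples,
    )


def repeated_cv(
    table: pd.DataFrame,
    split_config: SplitConfig | None = None,
    forest_config: ForestConfig | None = None,
) -> CVSummary:
    """K independent split → train → evaluate cycles on the true labels."""
    return _run_repeats(
        table,
        split_config or SplitConfig(),
        forest_config or ForestConfig(),
        shuffle_test_labels=False,
    )


def shuffle_null(
    table: pd.DataFrame,
    split_config: SplitConfig | None = None,
    forest_config: ForestConfig | None = None,
    null_method: str = "assign",
) -> CVSummary:
    """The overtraining control: randomize test labels before evaluation.

    Training is identical to :func:`repeated_cv` (true training labels);
    only the held-out labels are randomized, so any apparent skill left
    in the metrics would indicate information leakage.  A sound pipeline
    yields AUC 0.5 and, under the default ``assign`` randomization, 50 %
    accuracy, sensitivity and specificity (see ``_randomize_labels`` for
    the ``permute`` alternative, which preserves the class imbalance).
    """
    return _run_repeats(
        table,
        split_config or SplitConfig(),
        forest_config or ForestConfig(),
        shuffle_test_labels=True,
        null_method=null_method,
    )


def anova_significance(actual: CVSummary, null: CVSummary) -> SignificanceResult:
    """One-way ANOVA between the actual and null AUC samples."""
    a = np.asarray(actual.auc_samples, dtype=float)
    b = np.asarray(null.auc_samples, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two AUC samples")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return SignificanceResult(0.0, 1.0, (a.size, b.size))
        return SignificanceResult(
            float("inf"), float("nan"), (a.size, b.size)
        )
    f, p = stats.f_oneway(a, b)
    return SignificanceResult(float(f), float(p), (a.size, b.size))


class RepeatedSplitValidator(BaseEstimator):
    """Estimator-style front end to the repeated-split protocol.

    ``fit(table)`` runs the actual-label validation and, when
    ``with_null``, the shuffle-null control and the ANOVA comparison.
    Fitted attributes: ``summary_``, ``null_summary_``, ``anova_``.
    """

    def __init__(
        self,
        train_fraction: float = 0.7,
        k_repeats: int = 500,
        base_seed: int = 0,
        stratified: bool = True,
        n_trees: int = 100,
        max_features: str | int | float = "sqrt",
        min_leaf_size: int = 1,
        with_null: bool = True,
    ):
        self.train_fraction = train_fraction
        self.k_repeats = k_repeats
        self.base_seed = base_seed
        self.stratified = stratified
        self.n_trees = n_trees
        self.max_features = max_features
        self.min_leaf_size = min_leaf_size
        self.with_null = with_null

    def fit(self, X: pd.DataFrame, y=None):
        split = SplitConfig(
            train_fraction=self.train_fraction,
            k_repeats=self.k_repeats,
            base_seed=self.base_seed,
            stratified=self.stratified,
        )
        forest = ForestConfig(
            n_trees=self.n_trees,
            max_features=self.max_features,
            min_leaf_size=self.min_leaf_size,
        )
        self.summary_ = repeated_cv(X, split, forest)
        if self.with_null:
            self.null_summary_ = shuffle_null(X, split, forest)
            self.anova_ = anova_significance(self.summary_, self.null_summary_)
        return self
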