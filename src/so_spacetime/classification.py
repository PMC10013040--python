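"""Binary classifier battery for Global vs non-Global depth profiles.

Performance is scored with the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with the convention that a non-positive square-root argument yields
MCC = 0. MCC lives in [-1, 1] and is robust to the class imbalance typical
of these datasets (non-Global SOs outnumber Global ones), which is why it
is the metric of record here; no resampling is applied.

The battery is a registry of 30 named scikit-learn-backed learners
spanning the classical categories (decision trees, discriminant analysis,
logistic regression, naive Bayes, SVMs, nearest neighbors, ensembles,
small neural networks), each preceded by a train-split-fitted z-scoring
step. ``DEFAULT_BATTERY`` is a faster 16-learner subset. Validation
schemes: stratified 5-fold cross-validation with per-fold confusions
summed before one MCC computation (per-fold-mean mode available),
stratified 25% holdout, or train-equals-test on the full dataset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .depth_embedding import feature_names

MIN_CLASS_EVENTS = 5
SCHEMES = ("cv5", "holdout25", "full")


@dataclass
class ConfusionCounts:
    """Binary confusion counts; the positive class is Global."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient with the zero-denominator default.

    When any marginal of the confusion matrix is zero the square-root
    argument is not strictly positive and the coefficient defaults to 0.
    """
    denom_arg = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom_arg <= 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom_arg)


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    return ConfusionCounts(
        tp=int(np.sum(y_true & y_pred)),
        tn=int(np.sum(~y_true & ~y_pred)),
        fp=int(np.sum(~y_true & y_pred)),
        fn=int(np.sum(y_true & ~y_pred)),
    )


def mcc_from_predictions(y_true, y_pred) -> float:
    return mcc(confusion_from_predictions(y_true, y_pred))


# ---------------------------------------------------------------------------
# learners missing from scikit-learn


class KernelNaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes with per-feature Gaussian kernel density estimates.

    Class-conditional densities are products of univariate KDEs with
    Scott's-rule bandwidths, the kernel-smoothed analogue of Gaussian
    naive Bayes.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self._train = {}
        self._bw = {}
        self._logprior = {}
        n, p = X.shape
        for c in self.classes_:
            Xc = X[y == c]
            sd = Xc.std(axis=0, ddof=1)
            sd[~np.isfinite(sd) | (sd == 0)] = 1e-6
            self._train[c] = Xc
            self._bw[c] = sd * Xc.shape[0] ** (-1.0 / 5.0)  # Scott, univariate
            self._logprior[c] = np.log(Xc.shape[0] / n)
        return self

    def _joint_log_likelihood(self, X):
        X = np.asarray(X, dtype=float)
        out = np.empty((X.shape[0], len(self.classes_)))
        for j, c in enumerate(self.classes_):
            T, h = self._train[c], self._bw[c]
            ll = np.zeros(X.shape[0])
            for f in range(X.shape[1]):
                z = (X[:, f, None] - T[None, :, f]) / h[f]
                dens = np.exp(-0.5 * z**2).mean(axis=1) / (h[f] * np.sqrt(2 * np.pi))
                ll += np.log(np.clip(dens, 1e-300, None))
            out[:, j] = ll + self._logprior[c]
        return out

    def predict(self, X):
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]


class UndersampledBoost(BaseEstimator, ClassifierMixin):
    """AdaBoost on a seeded random undersample of the majority class."""

    def __init__(self, n_estimators: int = 30, random_state: int | None = None):
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        rng = np.random.default_rng(self.random_state)
        classes, counts = np.unique(y, return_counts=True)
        n_min = counts.min()
        keep = np.concatenate(
            [rng.choice(np.flatnonzero(y == c), size=n_min, replace=False)
             for c in classes]
        )
        self._model = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=2),
            n_estimators=self.n_estimators,
            random_state=self.random_state,
        ).fit(X[keep], y[keep])
        self.classes_ = self._model.classes_
        return self

    def predict(self, X):
        return self._model.predict(X)


# ---------------------------------------------------------------------------
# the registry: 30 named learners over 8 categories


def _make_registry():
    def knn(**kw):
        return lambda seed: KNeighborsClassifier(**kw)

    def mlp(layers):
        return lambda seed: MLPClassifier(
            hidden_layer_sizes=layers, max_iter=400, random_state=seed
        )

    reg = {
        # Decision Trees
        "fine_tree": lambda seed: DecisionTreeClassifier(max_leaf_nodes=100, random_state=seed),
        "medium_tree": lambda seed: DecisionTreeClassifier(max_leaf_nodes=20, random_state=seed),
        "coarse_tree": lambda seed: DecisionTreeClassifier(max_leaf_nodes=4, random_state=seed),
        # Discriminant Analysis
        "lda": lambda seed: LinearDiscriminantAnalysis(),
        "qda": lambda seed: QuadraticDiscriminantAnalysis(reg_param=1e-6),
        # Logistic Regression
        "logistic": lambda seed: LogisticRegression(max_iter=1000),
        # Naive Bayes
        "gaussian_nb": lambda seed: GaussianNB(),
        "kernel_nb": lambda seed: KernelNaiveBayes(),
        # Support Vector Machines
        "linear_svm": lambda seed: SVC(kernel="linear", random_state=seed),
        "quadratic_svm": lambda seed: SVC(kernel="poly", degree=2, random_state=seed),
        "cubic_svm": lambda seed: SVC(kernel="poly", degree=3, random_state=seed),
        "fine_gaussian_svm": lambda seed: SVC(kernel="rbf", gamma="scale", C=10.0, random_state=seed),
        "medium_gaussian_svm": lambda seed: SVC(kernel="rbf", gamma="scale", random_state=seed),
        "coarse_gaussian_svm": lambda seed: SVC(kernel="rbf", gamma="scale", C=0.1, random_state=seed),
        # Nearest Neighbors
        "fine_knn": knn(n_neighbors=1),
        "medium_knn": knn(n_neighbors=10),
        "coarse_knn": knn(n_neighbors=100),
        "cosine_knn": knn(n_neighbors=10, metric="cosine"),
        "cubic_knn": knn(n_neighbors=10, metric="minkowski", p=3),
        "weighted_knn": knn(n_neighbors=10, weights="distance"),
        # Ensembles
        "boosted_trees": lambda seed: AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=2),
            n_estimators=30, random_state=seed),
        "bagged_trees": lambda seed: BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            n_estimators=30, random_state=seed),
        "subspace_discriminant": lambda seed: BaggingClassifier(
            estimator=LinearDiscriminantAnalysis(),
            n_estimators=30, max_features=0.5, bootstrap=False, random_state=seed),
        "subspace_knn": lambda seed: BaggingClassifier(
            estimator=KNeighborsClassifier(n_neighbors=1),
            n_estimators=30, max_features=0.5, bootstrap=False, random_state=seed),
        "rus_boosted_trees": lambda seed: UndersampledBoost(random_state=seed),
        # Neural Networks
        "narrow_nn": mlp((10,)),
        "medium_nn": mlp((25,)),
        "wide_nn": mlp((100,)),
        "bilayered_nn": mlp((10, 10)),
        "trilayered_nn": mlp((10, 10, 10)),
    }
    return reg


ALGORITHM_REGISTRY = _make_registry()

#: Fast default subset covering every category.
DEFAULT_BATTERY = (
    "fine_tree", "medium_tree", "coarse_tree",
    "lda", "qda", "logistic", "gaussian_nb",
    "linear_svm", "fine_gaussian_svm", "cubic_svm",
    "fine_knn", "medium_knn", "cosine_knn", "cubic_knn", "weighted_knn",
    "bagged_trees", "subspace_knn",
)


def make_stub_battery(n: int) -> list:
    """``n`` trivially fast learners, for bookkeeping/smoke runs."""
    return [
        (f"stub_{i:02d}", lambda seed, i=i: DummyClassifier(strategy="most_frequent"))
        for i in range(n)
    ]


@dataclass
class ClassifierResult:
    """Outcome of one (algorithm, dataset, scheme) cell of the battery."""

    algorithm: str
    dataset: str
    stage: str
    scheme: str
    confusion: ConfusionCounts | None
    mcc: float
    n_features: int
    seed: int
    skipped: bool = False
    skip_reason: str = ""


def _resolve_algorithms(algorithms):
    if algorithms is None:
        algorithms = DEFAULT_BATTERY
    resolved = []
    for a in algorithms:
        if isinstance(a, str):
            resolved.append((a, ALGORITHM_REGISTRY[a]))
        else:
            resolved.append(tuple(a))
    return resolved


def _pipeline(factory, seed):
    return Pipeline([("scale", StandardScaler()), ("clf", factory(seed))])


def _score_dataset(X, y, factory, scheme, seed, fold_mode):
    if scheme == "cv5":
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        confusions, fold_mccs = [], []
        for tr, te in skf.split(X, y):
            model = _pipeline(factory, seed).fit(X[tr], y[tr])
            c = confusion_from_predictions(y[te], model.predict(X[te]))
            confusions.append(c)
            fold_mccs.append(mcc(c))
        total = confusions[0]
        for c in confusions[1:]:
            total = total + c
        value = mcc(total) if fold_mode == "pooled" else float(np.mean(fold_mccs))
        return total, value
    if scheme == "holdout25":
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, test_size=0.25, stratify=y, random_state=seed
        )
        model = _pipeline(factory, seed).fit(Xtr, ytr)
        c = confusion_from_predictions(yte, model.predict(Xte))
        return c, mcc(c)
    if scheme == "full":
        model = _pipeline(factory, seed).fit(X, y)
        c = confusion_from_predictions(y, model.predict(X))
        return c, mcc(c)
    raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")


def train_battery(
    profiles: pd.DataFrame,
    algorithms=None,
    scheme: str = "cv5",
    seed: int = 0,
    per_individual: bool = False,
    features=None,
    fold_mode: str = "pooled",
) -> list:
    """Train and score every (algorithm, dataset) cell.

    ``profiles`` is a depth-profile table (51 feature columns plus
    participant / stage / is_global labels). With ``per_individual`` each
    participant is a dataset; otherwise all rows pool into one. Datasets
    with fewer than 5 events in either class are recorded as skipped, not
    raised. ``features`` restricts the feature columns (names or indices).

    Returns a list of :class:`ClassifierResult`.
    """
    all_feats = [c for c in feature_names() if c in profiles.columns]
    if features is None:
        feats = all_feats
    else:
        feats = [all_feats[f] if isinstance(f, (int, np.integer)) else f for f in features]
        if not feats:
            raise ValueError("feature subset must be non-empty")
    algos = _resolve_algorithms(algorithms)
    if per_individual:
        datasets = [(str(p), g) for p, g in profiles.groupby("participant", observed=True)]
    else:
        datasets = [("pooled", profiles)]

    results = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence, QDA collinearity
        for ds_name, df in datasets:
            stage = df["stage"].iloc[0] if df["stage"].nunique() == 1 else "mixed"
            y = df["is_global"].to_numpy(dtype=bool)
            X = df[feats].to_numpy(dtype=float)
            n_pos, n_neg = int(y.sum()), int((~y).sum())
            if min(n_pos, n_neg) < MIN_CLASS_EVENTS:
                for name, _ in algos:
                    results.append(ClassifierResult(
                        algorithm=name, dataset=ds_name, stage=stage,
                        scheme=scheme, confusion=None, mcc=float("nan"),
                        n_features=len(feats), seed=seed, skipped=True,
                        skip_reason=f"class counts {n_pos}/{n_neg} below "
                                    f"{MIN_CLASS_EVENTS}",
                    ))
                continue
            for name, factory in algos:
                conf, value = _score_dataset(X, y, factory, scheme, seed, fold_mode)
                results.append(ClassifierResult(
                    algorithm=name, dataset=ds_name, stage=stage, scheme=scheme,
                    confusion=conf, mcc=value, n_features=len(feats), seed=seed,
                ))
    return results


def retrain_reduced(
    profiles: pd.DataFrame,
    feature_subset,
    algorithms=None,
    scheme: str = "holdout25",
    seed: int = 0,
    per_individual: bool = False,
    fold_mode: str = "pooled",
) -> pd.DataFrame:
    """Full-feature vs reduced-feature comparison under one protocol.

    Runs the battery twice - on all 51 features and on ``feature_subset`` -
    with identical seeds and splits, and returns a paired table with the
    per-algorithm MCC delta (reduced minus full).
    """
    full = train_battery(profiles, algorithms, scheme, seed,
                         per_individual=per_individual, fold_mode=fold_mode)
    reduced = train_battery(profiles, algorithms, scheme, seed,
                            per_individual=per_individual, features=feature_subset,
                            fold_mode=fold_mode)
    ft = results_table(full).rename(columns={"mcc": "mcc_full"})
    rt = results_table(reduced).rename(columns={"mcc": "mcc_reduced"})
    out = ft[["algorithm", "dataset", "stage", "scheme", "mcc_full"]].merge(
        rt[["algorithm", "dataset", "mcc_reduced", "n_features"]],
        on=["algorithm", "dataset"],
    )
    out["mcc_delta"] = out["mcc_reduced"] - out["mcc_full"]
    return out


def results_table(results) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "algorithm": r.algorithm,
            "dataset": r.dataset,
            "stage": r.stage,
            "scheme": r.scheme,
            "tp": r.confusion.tp if r.confusion else np.nan,
            "tn": r.confusion.tn if r.confusion else np.nan,
            "fp": r.confusion.fp if r.confusion else np.nan,
            "fn": r.confusion.fn if r.confusion else np.nan,
            "mcc": r.mcc,
            "n_features": r.n_features,
            "seed": r.seed,
            "skipped": r.skipped,
        })
    return pd.DataFrame(rows)
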