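"""Univariate chi-square ranking of depth-profile features.

Each of the 51 region-by-time features is scored by a chi-square test of
independence between its (quantile-discretized) values and the
Global/non-Global label; the score is -log10 of the p-value, so it grows
with the evidence that the two SO classes assume different values on that
feature. Raw score magnitudes scale with the dataset size, so
per-individual rankings are normalized to unit sum before averaging across
individuals; the number of retained top features is chosen at the largest
gap between consecutive sorted scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .depth_embedding import feature_names

P_CLAMP = 1e-300  # perfect separations underflow the chi-square p-value


@dataclass
class FeatureRanking:
    """Scores (-log10 p) per feature, with ordering helpers."""

    scores: np.ndarray
    names: list = field(default_factory=feature_names)
    mode: str = "pooled"   # individual | pooled | aggregated
    sem: np.ndarray | None = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.names) != self.scores.size:
            raise ValueError("one name per score required")

    @property
    def normalized(self) -> np.ndarray:
        s = self.scores.sum()
        return self.scores / s if s > 0 else self.scores

    @property
    def order(self) -> np.ndarray:
        """Permutation sorting scores descending (stable)."""
        return np.argsort(-self.scores, kind="stable")

    @property
    def cutoff_index(self) -> int:
        return gap_cutoff(self)

    def top_features(self, k: int | None = None) -> list:
        k = self.cutoff_index if k is None else k
        return [self.names[i] for i in self.order[:k]]


def _quantile_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="right")


def _merge_small_expected(table: np.ndarray, min_expected: float = 5.0) -> np.ndarray:
    """Merge adjacent bin columns until all expected counts reach 5."""
    table = table.copy()
    while table.shape[1] > 2:
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        small = np.flatnonzero(expected.min(axis=0) < min_expected)
        if small.size == 0:
            break
        j = small[0]
        k = j + 1 if j + 1 < table.shape[1] else j - 1
        table[:, min(j, k)] += table[:, max(j, k)]
        table = np.delete(table, max(j, k), axis=1)
    return table


def chi2_feature_score(x: np.ndarray, y: np.ndarray, n_bins: int = 10) -> float:
    """-log10 p of a chi-square independence test for one feature.

    The feature is discretized into up to ``n_bins`` quantile bins on the
    combined sample (scale-free), cells with expected count < 5 are merged
    with neighbors, and the test runs against the binary label. Constant
    features score 0; underflowing p-values are clamped at 1e-300.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=bool)
    bins = _quantile_bins(x, n_bins)
    if np.unique(bins).size < 2:
        return 0.0
    table = pd.crosstab(y, bins).to_numpy()
    if table.shape[0] < 2:
        return 0.0
    table = _merge_small_expected(table)
    if table.shape[1] < 2 or (table.sum(axis=0) == 0).any():
        return 0.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(-np.log10(max(p, P_CLAMP)))


def chi2_rank(
    profiles: pd.DataFrame,
    labels=None,
    n_bins: int = 10,
    mode: str = "pooled",
) -> FeatureRanking:
    """Rank all features of a depth-profile table by chi-square separation.

    ``profiles`` may be a labeled table (with an ``is_global`` column) or a
    bare feature matrix with ``labels`` supplied separately.
    """
    if labels is None:
        labels = profiles["is_global"].to_numpy(dtype=bool)
    names = [c for c in feature_names() if c in profiles.columns]
    if not names:  # bare matrix
        names = list(profiles.columns)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present for ranking")
    scores = np.array(
        [chi2_feature_score(profiles[c].to_numpy(float), y, n_bins) for c in names]
    )
    return FeatureRanking(scores=scores, names=names, mode=mode)


def rank_per_individual(profiles: pd.DataFrame, n_bins: int = 10) -> list:
    """One ranking per participant (participants lacking a class are skipped)."""
    out = []
    for p, df in profiles.groupby("participant", observed=True):
        y = df["is_global"].to_numpy(dtype=bool)
        if y.all() or not y.any():
            warnings.warn(f"participant {p} lacks one class; skipped", stacklevel=2)
            continue
        r = chi2_rank(df, n_bins=n_bins, mode="individual")
        out.append(r)
    return out


def normalize_and_aggregate(rankings) -> FeatureRanking:
    """Average unit-sum-normalized per-individual rankings feature-wise.

    Per-individual score vectors are divided by their total (removing the
    dependence on each individual's event count) and averaged; the SEM per
    feature is kept for error bars. All-zero individual vectors are
    excluded with a warning.
    """
    kept = []
    for r in rankings:
        if r.scores.sum() <= 0:
            warnings.warn("excluding an all-zero individual ranking", stacklevel=2)
            continue
        kept.append(r.normalized)
    if not kept:
        raise ValueError("no individual ranking with positive total score")
    arr = np.vstack(kept)
    sem = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]) if arr.shape[0] > 1 else np.zeros(arr.shape[1])
    return FeatureRanking(
        scores=arr.mean(axis=0), names=rankings[0].names, mode="aggregated", sem=sem
    )


def gap_cutoff(ranking) -> int:
    """Retain the top features up to the largest drop in sorted scores.

    With scores sorted descending, gaps are the consecutive differences;
    the cutoff is argmax-gap + 1 (ties to the smallest index). If every
    gap is zero there is no structure: all features are retained, with a
    warning.
    """
    scores = ranking.scores if isinstance(ranking, FeatureRanking) else np.asarray(ranking, float)
    if scores.size < 2:
        raise ValueError("need at least 2 features")
    s = np.sort(scores)[::-1]
    gaps = s[:-1] - s[1:]
    if np.all(gaps == 0):
        warnings.warn("all scores equal; no gap cutoff, retaining all features",
                      stacklevel=2)
        return int(scores.size)
    return int(np.argmax(gaps)) + 1


def gap_profile(ranking) -> np.ndarray:
    """The consecutive-gap sequence itself (for inspecting alternate peaks)."""
    scores = ranking.scores if isinstance(ranking, FeatureRanking) else np.asarray(ranking, float)
    s = np.sort(scores)[::-1]
    return s[:-1] - s[1:]


def rank_report(aggregated: FeatureRanking, pooled: FeatureRanking,
                cutoffs: tuple | None = None) -> pd.DataFrame:
    """Side-by-side listing of features above each cutoff.

    ``cutoffs`` overrides the gap cutoffs as (aggregated, pooled); the
    report flags an unstable top set when a ranking has no positive scores.
    """
    c_agg = cutoffs[0] if cutoffs else aggregated.cutoff_index
    c_pool = cutoffs[1] if cutoffs else pooled.cutoff_index
    top_a = aggregated.top_features(c_agg) if aggregated.scores.sum() > 0 else []
    top_p = pooled.top_features(c_pool) if pooled.scores.sum() > 0 else []
    if not top_a and not top_p:
        warnings.warn("no stable top feature set (all scores zero)", stacklevel=2)
    n = max(len(top_a), len(top_p), 1)
    pad = lambda lst: lst + [""] * (n - len(lst))
    return pd.DataFrame({
        "rank": np.arange(1, n + 1),
        "across_individuals": pad(top_a),
        "pooled_dataset": pad(top_p),
    })


def trough_bin_fraction(features) -> float:
    """Fraction of the given feature names lying in the trough time bin."""
    feats = list(features)
    if not feats:
        return 0.0
    return float(np.mean([f.endswith("_trough") for f in feats]))
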