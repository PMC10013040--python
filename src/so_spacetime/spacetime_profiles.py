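"""Scalp space-time typing of slow oscillations.

Every detected SO is summarized by a binary co-detection vector over the
electrode montage: entry *e* is 1 when electrode *e* shows an SO trough
within +/-400 ms of the reference event's trough. The co-detection matrix
is clustered with k-means under Hamming distance (best of 200 seeded
replicates, kmeans++ initialization, empty clusters dropped), and each
cluster is labeled Global, Frontal or Local from its mean scalp topography.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

SO_TYPES = ("Global", "Frontal", "Local")


@dataclass
class CoDetectionMatrix:
    """Events x electrodes binary co-detection matrix."""

    matrix: np.ndarray            # (n_events, n_channels) of {0, 1}
    channel_labels: list
    events: list                  # SoEvent, row order
    stage: str = "S2"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("co-detection entries must be binary")


@dataclass
class SoTypeAssignment:
    """Per-event cluster id and Global/Frontal/Local label."""

    cluster_id: np.ndarray        # per event
    cluster_types: dict           # cluster id -> type string
    centroid_topographies: np.ndarray  # (n_clusters, n_channels) mean co-detection

    @property
    def so_type(self) -> np.ndarray:
        return np.array([self.cluster_types[c] for c in self.cluster_id], dtype=object)

    @property
    def is_global(self) -> np.ndarray:
        return self.so_type == "Global"


def default_frontal_channels(labels) -> np.ndarray:
    """Boolean mask of frontal electrodes: 10-20 Fp/AF/F rows (not FC/FT)."""
    mask = []
    for lab in labels:
        l = str(lab)
        frontal = l.startswith(("Fp", "AF", "FP")) or (
            l.startswith("F") and len(l) > 1 and (l[1].isdigit() or l[1] in "zZ")
        )
        mask.append(frontal)
    return np.array(mask, dtype=bool)


def build_codetection(events, channel_labels, window: float = 0.4,
                      stage: str | None = None) -> CoDetectionMatrix:
    """Binary co-detection matrix: one row per event, one column per electrode.

    Entry (i, e) is 1 iff electrode *e* has any SO trough within
    ``+/-window`` seconds of event *i*'s trough. The reference electrode's
    own column is always 1 (an event co-detects itself). Events should come
    from one participant and one stage.
    """
    if stage is not None:
        events = [e for e in events if e.stage == stage]
    labels = list(channel_labels)
    col = {lab: j for j, lab in enumerate(labels)}
    troughs = {lab: [] for lab in labels}
    for e in events:
        troughs[e.channel].append(e.trough_time)
    troughs = {lab: np.sort(ts) for lab, ts in troughs.items()}

    M = np.zeros((len(events), len(labels)), dtype=np.uint8)
    for i, e in enumerate(events):
        for lab, ts in troughs.items():
            if ts.size == 0:
                continue
            k = np.searchsorted(ts, e.trough_time)
            near = False
            if k < ts.size and ts[k] - e.trough_time <= window + 1e-12:
                near = True
            if k > 0 and e.trough_time - ts[k - 1] <= window + 1e-12:
                near = True
            if near:
                M[i, col[lab]] = 1
        M[i, col[e.channel]] = 1
    return CoDetectionMatrix(matrix=M, channel_labels=labels, events=list(events),
                             stage=stage or (events[0].stage if events else "S2"))


# ---------------------------------------------------------------------------
# Hamming k-means


def _hamming_distances(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Pairwise Hamming distance (proportion of mismatched bits)."""
    Xf = X.astype(float)
    Cf = C.astype(float)
    mismatch = Xf @ (1.0 - Cf.T) + (1.0 - Xf) @ Cf.T
    return mismatch / X.shape[1]


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centroids = [X[rng.integers(n)]]
    for _ in range(1, k):
        D = _hamming_distances(X, np.array(centroids)).min(axis=1)
        w = D**2
        if w.sum() <= 0:
            idx = rng.integers(n)
        else:
            idx = rng.choice(n, p=w / w.sum())
        centroids.append(X[idx])
    return np.array(centroids)


def hamming_kmeans(
    X: np.ndarray,
    k: int,
    replicates: int = 200,
    max_iter: int = 10000,
    seed: int | None = 0,
    drop_empty: bool = True,
):
    """Binary k-means under Hamming distance.

    Runs ``replicates`` seeded kmeans++ initializations and keeps the
    assignment with the lowest total within-cluster Hamming distance (ties
    go to the lowest replicate index). Centroids are per-column majority
    votes with ties resolved to 1; empty clusters are dropped when
    ``drop_empty``. Assignment ties go to the lowest cluster index.

    Returns ``(labels, centroids, inertia)``.
    """
    X = np.asarray(X)
    if k < 2:
        raise ValueError("k must be at least 2")
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} rows, got {X.shape[0]}")
    root = np.random.default_rng(seed)
    best = None
    for rep in range(replicates):
        rng = np.random.default_rng(root.integers(2**31))
        C = _kmeanspp_init(X, k, rng)
        for _ in range(max_iter):
            D = _hamming_distances(X, C)
            labels = D.argmin(axis=1)
            keep = []
            for j in range(C.shape[0]):
                members = X[labels == j]
                if members.size == 0:
                    if not drop_empty:
                        keep.append(C[j])
                    continue
                # majority vote per column, ties -> 1
                keep.append((members.mean(axis=0) >= 0.5).astype(np.uint8))
            newC = np.array(keep)
            if newC.shape == C.shape and np.array_equal(newC, C):
                break
            C = newC
            if C.shape[0] < 1:
                break
        D = _hamming_distances(X, C)
        labels = D.argmin(axis=1)
        inertia = float(D[np.arange(X.shape[0]), labels].sum())
        if best is None or inertia < best[2] - 1e-12:
            # relabel clusters to consecutive ids in appearance order
            uniq = pd.unique(labels)
            remap = {c: i for i, c in enumerate(uniq)}
            best = (
                np.array([remap[c] for c in labels]),
                C[uniq],
                inertia,
            )
    return best


def label_clusters(
    matrix: CoDetectionMatrix,
    cluster_ids: np.ndarray,
    frontal_channels: np.ndarray | None = None,
    theta_global: float = 0.8,
    theta_frontal: float = 0.6,
) -> SoTypeAssignment:
    """Name each cluster Global, Frontal or Local from its mean topography.

    A cluster is Global when its grand-mean co-detection rate is at least
    ``theta_global``; otherwise Frontal when the mean over frontal
    electrodes reaches ``theta_frontal`` while the non-frontal mean stays
    below it; otherwise Local.
    """
    if frontal_channels is None:
        frontal_channels = default_frontal_channels(matrix.channel_labels)
    frontal_channels = np.asarray(frontal_channels, dtype=bool)
    ids = np.asarray(cluster_ids)
    uniq = np.unique(ids)
    centroids = np.array([matrix.matrix[ids == c].mean(axis=0) for c in uniq])
    types = {}
    for c, topo in zip(uniq, centroids):
        if topo.mean() >= theta_global:
            types[int(c)] = "Global"
        elif (
            frontal_channels.any()
            and topo[frontal_channels].mean() >= theta_frontal
            and (not (~frontal_channels).any() or topo[~frontal_channels].mean() < theta_frontal)
        ):
            types[int(c)] = "Frontal"
        else:
            types[int(c)] = "Local"
    return SoTypeAssignment(
        cluster_id=ids, cluster_types=types, centroid_topographies=centroids
    )


def classify_events(
    events,
    channel_labels,
    k: int = 3,
    window: float = 0.4,
    replicates: int = 200,
    max_iter: int = 10000,
    seed: int | None = 0,
    frontal_channels=None,
    theta_global: float = 0.8,
    theta_frontal: float = 0.6,
    stage: str | None = None,
):
    """Co-detection + clustering + labeling in one call.

    Returns ``(CoDetectionMatrix, SoTypeAssignment)``.
    """
    mat = build_codetection(events, channel_labels, window=window, stage=stage)
    labels, _, _ = hamming_kmeans(
        mat.matrix, k=k, replicates=replicates, max_iter=max_iter, seed=seed
    )
    assignment = label_clusters(
        mat, labels, frontal_channels=frontal_channels,
        theta_global=theta_global, theta_frontal=theta_frontal,
    )
    return mat, assignment


def assignment_table(matrix: CoDetectionMatrix, assignment: SoTypeAssignment) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant": [e.participant for e in matrix.events],
            "channel": [e.channel for e in matrix.events],
            "stage": [e.stage for e in matrix.events],
            "trough_time": [e.trough_time for e in matrix.events],
            "cluster_id": assignment.cluster_id,
            "so_type": assignment.so_type,
            "is_global": assignment.is_global,
        }
    )


def type_fractions(assignments: pd.DataFrame):
    """Per participant-stage fractions of each SO type, with cohort summary.

    ``assignments`` needs columns participant, stage, so_type. Returns
    ``(per_participant, summary)`` where the summary holds mean and SEM of
    each fraction across participants per stage. Participant-stage cells
    with zero events simply do not appear (a warning names them if a
    participant is present in one stage but absent in another).
    """
    counts = (
        assignments.groupby(["participant", "stage", "so_type"], observed=True)
        .size()
        .unstack("so_type", fill_value=0)
    )
    for t in SO_TYPES:
        if t not in counts.columns:
            counts[t] = 0
    counts = counts[list(SO_TYPES)]
    fractions = counts.div(counts.sum(axis=1), axis=0).reset_index()

    participants = assignments["participant"].unique()
    for stage in assignments["stage"].unique():
        present = fractions.loc[fractions["stage"] == stage, "participant"]
        missing = set(participants) - set(present)
        if missing:
            warnings.warn(
                f"participants {sorted(missing)} have zero SOs in stage {stage}; "
                "excluded from that stage's fractions",
                stacklevel=2,
            )
    summary = (
        fractions.groupby("stage")[list(SO_TYPES)]
        .agg(["mean", "sem"])
    )
    return fractions, summary
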