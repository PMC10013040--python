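"""Co-detection matrices, Hamming k-means, cluster typing, fractions."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import rand_score

from so_spacetime.so_detection import SoEvent
from so_spacetime.spacetime_profiles import (
    build_codetection,
    CoDetectionMatrix,
    default_frontal_channels,
    hamming_kmeans,
    label_clusters,
    type_fractions,
)

CHANNELS = [f"C{i}" for i in range(10)]


def _event(channel, t, stage="S2", participant="p01"):
    return SoEvent(channel=channel, trough_time=t, pos2neg_zc=t - 0.3,
                   neg2pos_zc=t + 0.3, trough_voltage=-100.0, peak_voltage=25.0,
                   peak_to_peak=125.0, event_duration=1.0, stage=stage,
                   participant=participant)


def test_global_event_row_is_all_ones():
    events = [_event(c, 10.0 + 0.005 * i) for i, c in enumerate(CHANNELS)]
    mat = build_codetection(events, CHANNELS)
    assert mat.matrix.shape == (10, 10)
    assert mat.matrix.all()


def test_local_event_row_sum_matches_electrode_count():
    events = [_event("C1", 10.0), _event("C4", 10.1), _event("C7", 9.9)]
    mat = build_codetection(events, CHANNELS)
    assert (mat.matrix.sum(axis=1) == 3).all()


def test_same_electrode_events_outside_window_do_not_codetect():
    events = [_event("C2", 10.0), _event("C2", 10.5)]
    mat = build_codetection(events, CHANNELS)
    # each row sees only itself: 0.5 s exceeds the +/-400 ms window
    assert (mat.matrix.sum(axis=1) == 1).all()
    assert mat.matrix[0, 2] == 1 and mat.matrix[1, 2] == 1


def test_codetection_symmetry_between_codetected_events():
    events = [_event("C0", 10.0), _event("C5", 10.2)]
    mat = build_codetection(events, CHANNELS)
    assert mat.matrix[0, 5] == 1 and mat.matrix[1, 0] == 1


def _planted_rows(rng, n_channels=20):
    frontal = np.zeros(n_channels, dtype=int)
    frontal[:6] = 1
    rows, truth = [], []
    for _ in range(100):
        rows.append(np.ones(n_channels, dtype=int))
        truth.append(0)
    for _ in range(100):
        rows.append(frontal.copy())
        truth.append(1)
    for _ in range(100):
        r = np.zeros(n_channels, dtype=int)
        r[rng.choice(n_channels, 3, replace=False)] = 1
        rows.append(r)
        truth.append(2)
    return np.array(rows), np.array(truth)


def test_hamming_kmeans_recovers_planted_partition():
    rng = np.random.default_rng(42)
    X, truth = _planted_rows(rng)
    labels, centroids, inertia = hamming_kmeans(X, k=3, replicates=20, seed=0)
    assert rand_score(truth, labels) >= 0.95


def test_hamming_kmeans_identical_rows_collapse_to_one_cluster():
    X = np.ones((30, 8), dtype=int)
    labels, centroids, _ = hamming_kmeans(X, k=2, replicates=5, seed=1)
    assert len(np.unique(labels)) == 1
    assert centroids.shape[0] == 1  # empty cluster dropped


def test_hamming_kmeans_seed_determinism_and_k_guard():
    rng = np.random.default_rng(3)
    X = (rng.random((60, 12)) > 0.5).astype(int)
    a = hamming_kmeans(X, k=3, replicates=10, seed=7)
    b = hamming_kmeans(X, k=3, replicates=10, seed=7)
    assert np.array_equal(a[0], b[0])
    with pytest.raises(ValueError, match="k must be"):
        hamming_kmeans(X, k=1)
    with pytest.raises(ValueError, match="rows"):
        hamming_kmeans(X[:2], k=3)


@pytest.mark.parametrize(
    "topo_kind, expected",
    [("ones", "Global"), ("frontal", "Frontal"), ("sparse", "Local")],
)
def test_label_clusters_three_archetypes(topo_kind, expected):
    labels = ["Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2"]
    frontal = default_frontal_channels(labels)
    assert frontal.sum() == 4
    n = len(labels)
    if topo_kind == "ones":
        rows = np.ones((20, n), dtype=int)
    elif topo_kind == "frontal":
        rows = np.tile(frontal.astype(int), (20, 1))
    else:
        rows = np.zeros((20, n), dtype=int)
        rows[:, 0] = 1
    events = [_event(labels[0], 10.0 + 5 * i) for i in range(20)]
    mat = CoDetectionMatrix(matrix=rows, channel_labels=labels, events=events)
    asn = label_clusters(mat, np.zeros(20, dtype=int), frontal_channels=frontal)
    assert asn.cluster_types[0] == expected
    assert (asn.is_global == (expected == "Global")).all()


def test_frontal_channel_prefix_rule():
    labels = ["Fp1", "AF3", "F7", "Fz", "FC1", "FT7", "C3", "P4", "F4"]
    mask = default_frontal_channels(labels)
    assert list(np.array(labels)[mask]) == ["Fp1", "AF3", "F7", "Fz", "F4"]


def test_type_fractions_sum_to_one_and_handle_missing_types():
    df = pd.DataFrame({
        "participant": ["p01"] * 100,
        "stage": ["S2"] * 100,
        "so_type": ["Global"] * 50 + ["Local"] * 50,
    })
    fractions, summary = type_fractions(df)
    row = fractions.iloc[0]
    assert row["Global"] == 0.5 and row["Frontal"] == 0.0 and row["Local"] == 0.5
    assert np.isclose(fractions[["Global", "Frontal", "Local"]].sum(axis=1), 1).all()


def test_type_fractions_single_type_and_zero_so_participant_warning():
    df = pd.DataFrame({
        "participant": ["p01"] * 10 + ["p02"] * 10 + ["p02"] * 5,
        "stage": ["S2"] * 10 + ["S2"] * 10 + ["SWS"] * 5,
        "so_type": ["Global"] * 20 + ["Local"] * 5,
    })
    with pytest.warns(UserWarning, match="p01.*SWS"):
        fractions, _ = type_fractions(df)
    p1 = fractions[(fractions.participant == "p01") & (fractions.stage == "S2")]
    assert p1["Global"].iloc[0] == 1.0


def test_planted_cohort_fractions_recovered_within_binomial_error():
    # 500 SO per participant at (0.3, 0.2, 0.5); 3 binomial SE tolerance
    rng = np.random.default_rng(8)
    frames = []
    for p in range(5):
        types = rng.choice(["Global", "Frontal", "Local"], size=500,
                           p=[0.3, 0.2, 0.5])
        frames.append(pd.DataFrame({
            "participant": f"p{p:02d}", "stage": "S2", "so_type": types,
        }))
    fractions, summary = type_fractions(pd.concat(frames))
    for typ, p_true in zip(("Global", "Frontal", "Local"), (0.3, 0.2, 0.5)):
        se = np.sqrt(p_true * (1 - p_true) / 500)
        assert np.abs(fractions[typ] - p_true).max() < 4 * se
        cohort_mean = summary.loc["S2", (typ, "mean")]
        assert abs(cohort_mean - p_true) < 3 * se / np.sqrt(5)
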