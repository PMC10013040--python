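"""Generators: seeded determinism, planted truth, toy forward model."""

import numpy as np
import pytest
from scipy import stats

from so_spacetime import synthetic_data as syn
from so_spacetime.depth_embedding import REGIONS, feature_index, feature_names
from so_spacetime.so_detection import bandpass


def _one_global_spec(noise=0.0, seed=3):
    spec = syn.SyntheticSpec(noise_sigma=noise, seed=seed, stage_plan=[("S2", 60.0)])
    n = spec.n_channels
    rng = np.random.default_rng(1)
    spec.so_plan = [
        syn.PlantedSo(
            trough_time=30.0,
            so_type="Global",
            electrode_set=np.arange(n),
            per_electrode_delay=rng.uniform(-0.3, 0.3, n),
            trough_amplitude=-100.0,
        )
    ]
    spec.validate_plan()
    return spec


def test_noiseless_global_trough_lands_at_planted_time_per_electrode():
    spec = _one_global_spec()
    rec = syn.generate_eeg(spec)
    so = spec.so_plan[0]
    for e, d in zip(so.electrode_set, so.per_electrode_delay):
        filt = bandpass(rec.data[e], rec.sampling_rate)
        tmin = np.argmin(filt) / rec.sampling_rate
        assert abs(tmin - (so.trough_time + d)) <= 1.0 / rec.sampling_rate + 1e-9


def test_seeded_determinism_bit_for_bit():
    a = syn.generate_eeg(_one_global_spec(noise=20.0, seed=7))
    b = syn.generate_eeg(_one_global_spec(noise=20.0, seed=7))
    assert np.array_equal(a.data, b.data)
    c = syn.generate_eeg(_one_global_spec(noise=20.0, seed=8))
    assert not np.array_equal(a.data, c.data)


def test_empty_plan_gives_pure_noise_and_stage_hypnogram():
    spec = syn.SyntheticSpec(noise_sigma=0.0, seed=0, stage_plan=[("SWS", 60.0)])
    rec = syn.generate_eeg(spec)
    assert not rec.data.any()
    assert set(rec.hypnogram) == {"SWS"}


def test_overlapping_plants_rejected():
    spec = syn.SyntheticSpec(noise_sigma=0.0, seed=0, stage_plan=[("S2", 60.0)])
    mk = lambda t: syn.PlantedSo(trough_time=t, so_type="Local",
                                 electrode_set=np.array([4]), duration=0.8)
    spec.so_plan = [mk(10.0), mk(10.5)]
    with pytest.raises(ValueError, match="overlap"):
        spec.validate_plan()


@pytest.mark.parametrize(
    "kwargs, match",
    [
        (dict(so_type="Global", electrode_set=np.arange(10)), "90%"),
        (dict(so_type="Frontal", electrode_set=np.array([30, 31])), "frontal"),
        (dict(so_type="Local", electrode_set=np.arange(20)), "20%"),
    ],
)
def test_type_invariants_enforced(kwargs, match):
    spec = syn.SyntheticSpec(noise_sigma=0.0, stage_plan=[("S2", 60.0)])
    spec.so_plan = [syn.PlantedSo(trough_time=30.0, **kwargs)]
    with pytest.raises(ValueError, match=match):
        spec.validate_plan()


def test_planted_so_field_validation():
    with pytest.raises(ValueError, match="-80"):
        syn.PlantedSo(trough_time=1.0, electrode_set=[0], trough_amplitude=-70.0)
    with pytest.raises(ValueError, match=r"\[0.3, 1.0\]"):
        syn.PlantedSo(trough_time=1.0, electrode_set=[0], duration=1.5)
    with pytest.raises(ValueError, match="400"):
        syn.PlantedSo(trough_time=1.0, electrode_set=[0],
                      per_electrode_delay=[0.5])


# -- head model -------------------------------------------------------------


def test_head_model_shapes_and_regions(head_model):
    assert head_model.leadfield.shape == (58, 85)
    assert len(np.unique(head_model.region_of_source)) == 17
    assert np.linalg.matrix_rank(head_model.leadfield) == 58


def test_head_model_determinism_and_single_source_regions():
    a = syn.generate_head_model(58, 5, seed=1)
    b = syn.generate_head_model(58, 5, seed=1)
    assert np.array_equal(a.leadfield, b.leadfield)
    one = syn.generate_head_model(16, 1, seed=2)
    counts = np.bincount(one.region_of_source)
    assert (counts == 1).all() and counts.size == 17


def test_head_model_rank_guard():
    with pytest.raises(ValueError, match="rank"):
        syn.generate_head_model(n_sensors=58, sources_per_region=3)


def test_forward_projection_matches_leadfield_product(head_model):
    rng = np.random.default_rng(0)
    S = rng.standard_normal((head_model.n_sources, 4))
    V = syn.project_sources(head_model, S)
    assert np.allclose(V, head_model.leadfield @ S)


# -- depth datasets ---------------------------------------------------------


def test_null_depth_dataset_classes_indistinguishable():
    df = syn.generate_depth_dataset(500, 500, [(REGIONS[0], "trough")], 0.0, seed=4)
    g = df[df.is_global]
    ng = df[~df.is_global]
    col = f"{REGIONS[0]}_trough"
    t, p = stats.ttest_ind(g[col], ng[col])
    assert p > 0.001  # no planted effect to find
    assert (df[feature_names()].to_numpy() >= 0).all()


def test_effect_concentrated_on_planted_features_t_score_oracle():
    feats = [(r, "trough") for r in REGIONS[:4]]
    df = syn.generate_depth_dataset(1000, 1000, feats, 2.0, seed=9)
    y = df["is_global"].to_numpy()
    tscores = np.array(
        [abs(stats.ttest_ind(df[c][y], df[c][~y]).statistic) for c in feature_names()]
    )
    planted = {feature_index(r, b) for r, b in feats}
    top4 = set(np.argsort(-tscores)[:4])
    assert top4 == planted


def test_depth_dataset_seed_determinism():
    a = syn.generate_depth_dataset(50, 50, [0, 1], 1.0, seed=5)
    b = syn.generate_depth_dataset(50, 50, [0, 1], 1.0, seed=5)
    assert a.equals(b)


def test_cohort_has_distinct_participants_with_shared_effect():
    df = syn.generate_depth_cohort(4, 30, 60, [(REGIONS[0], "trough")], 2.0, seed=6)
    assert df["participant"].nunique() == 4
    col = f"{REGIONS[0]}_trough"
    per = df.groupby(["participant", "is_global"], observed=True)[col].mean().unstack()
    assert (per[True] > per[False]).all()


# -- decoys -----------------------------------------------------------------


def test_decoy_waveforms_violate_their_single_criterion():
    rate = 500.0
    wave, off = syn.decoy_waveform("amplitude", rate)
    assert wave.min() > -80
    wave, _ = syn.decoy_waveform("p2p", rate)
    assert wave.max() - wave.min() < 80
    wave, _ = syn.decoy_waveform("zc_short", rate)
    assert (wave < 0).sum() / rate < 0.3
    wave, _ = syn.decoy_waveform("zc_long", rate)
    assert (wave < 0).sum() / rate > 1.0
    with pytest.raises(ValueError, match="decoy kind"):
        syn.decoy_waveform("nope", rate)
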