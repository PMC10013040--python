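import pytest

from so_spacetime import synthetic_data as syn


@pytest.fixture(scope="session")
def head_model():
    return syn.generate_head_model(n_sensors=58, sources_per_region=5, seed=1)


@pytest.fixture(scope="session")
def small_head_model():
    return syn.generate_head_model(n_sensors=16, sources_per_region=1, seed=2)


@pytest.fixture()
def quiet_spec():
    """Noiseless 2-minute S2 recording with one planted SO of each type."""
    spec = syn.SyntheticSpec(noise_sigma=0.0, seed=11, stage_plan=[("S2", 120.0)])
    spec.so_plan = syn.random_so_plan(spec, n_global=1, n_frontal=1, n_local=1,
                                      seed=5, t_end=110.0, spacing=10.0)
    spec.validate_plan()
    return spec


@pytest.fixture()
def quiet_recording(quiet_spec):
    return syn.generate_eeg(quiet_spec)


@pytest.fixture(scope="session")
def trough_effect_features():
    from so_spacetime.depth_embedding import REGIONS

    return [(r, "trough") for r in REGIONS[:15]]
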