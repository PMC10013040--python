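"""Synthetic inputs for the whole pipeline, with seeded reproducibility.

Three generators cover every input the analysis needs:

* :func:`generate_eeg` - multichannel scalp EEG (default 58 channels at
  500 Hz) with planted slow oscillations of known scalp type (Global,
  Frontal or Local), a hypnogram following a stage plan, and Gaussian (or
  optionally 1/f) background noise. The SO template is a half-sine down
  state followed by a half-sine up state, so a planted event satisfies the
  detection criteria by construction.
* :func:`generate_head_model` - a toy forward model: sensors on a sphere,
  sources grouped in 17 disjoint regional blobs, and an analytic
  distance-decay gain g = 1 / (eps + r^2). Deliberately not a boundary
  element model, but full sensor rank, so the inverse-kernel properties
  (including sLORETA's zero localization error) are exactly testable.
* :func:`generate_depth_dataset` - labeled 51-dimensional depth-profile
  vectors whose Global vs non-Global difference is confined to chosen
  region-time features at a chosen standardized effect size.

Planted truth is metadata: the analysis stages never read it; tests do.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .depth_embedding import REGIONS, feature_index, feature_names
from .sleep_io import EPOCH_SECONDS, EegRecording
from .spacetime_profiles import default_frontal_channels

SO_TYPES = ("Global", "Frontal", "Local")

#: 58-channel 10-20/10-10 montage (frontal rows first).
DEFAULT_CHANNELS = [
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO3", "POz", "PO4", "O1", "O2",
]


@dataclass
class PlantedSo:
    """One slow oscillation to plant: where, when and how big."""

    trough_time: float                 # s
    so_type: str = "Global"            # Global / Frontal / Local
    electrode_set: np.ndarray = None   # channel indices carrying the wave
    per_electrode_delay: np.ndarray = None  # s, |delay| <= 0.4
    trough_amplitude: float = -100.0   # uV, <= -80
    duration: float = 0.5              # s, down-state half-sine, in [0.3, 1.0]
    up_amplitude: float = 25.0         # uV, up-state half-sine peak
    up_duration: float = 0.5           # s

    def __post_init__(self):
        if self.so_type not in SO_TYPES:
            raise ValueError(f"so_type must be one of {SO_TYPES}")
        if self.trough_amplitude > -80.0:
            raise ValueError("trough_amplitude must be <= -80 uV")
        if not 0.3 <= self.duration <= 1.0:
            raise ValueError("duration must lie in [0.3, 1.0] s")
        self.electrode_set = np.atleast_1d(np.asarray(self.electrode_set, dtype=int))
        if self.per_electrode_delay is None:
            self.per_electrode_delay = np.zeros(self.electrode_set.size)
        self.per_electrode_delay = np.atleast_1d(
            np.asarray(self.per_electrode_delay, dtype=float)
        )
        if self.per_electrode_delay.size != self.electrode_set.size:
            raise ValueError("one delay per electrode required")
        if np.abs(self.per_electrode_delay).max(initial=0.0) > 0.4:
            raise ValueError("per-electrode delays must lie within +/-400 ms")

    @property
    def span(self) -> float:
        return self.duration + self.up_duration


@dataclass
class SyntheticSpec:
    """Everything :func:`generate_eeg` needs, seed included."""

    n_channels: int = 58
    sampling_rate: float = 500.0
    stage_plan: list = field(default_factory=lambda: [("S2", 300.0), ("SWS", 300.0)])
    so_plan: list = field(default_factory=list)
    noise_sigma: float = 15.0          # uV
    one_over_f: bool = False
    seed: int = 0
    channel_labels: list = None
    n_participants: int = 1
    participant: str = "p01"

    def __post_init__(self):
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.channel_labels is None:
            base = DEFAULT_CHANNELS
            if self.n_channels <= len(base):
                self.channel_labels = base[: self.n_channels]
            else:
                self.channel_labels = base + [
                    f"X{i}" for i in range(self.n_channels - len(base))
                ]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("one label per channel required")
        self.validate_plan()

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.stage_plan))

    @property
    def frontal_mask(self) -> np.ndarray:
        return default_frontal_channels(self.channel_labels)

    def validate_plan(self) -> None:
        """Type invariants and per-electrode overlap check for the SO plan."""
        frontal = self.frontal_mask
        n = self.n_channels
        per_electrode: dict = {}
        for so in self.so_plan:
            if so.electrode_set.min(initial=0) < 0 or so.electrode_set.max(initial=0) >= n:
                raise ValueError("electrode_set indices out of range")
            if so.so_type == "Global" and so.electrode_set.size < 0.9 * n:
                raise ValueError("Global SOs must cover >= 90% of channels")
            if so.so_type == "Frontal" and not frontal[so.electrode_set].all():
                raise ValueError("Frontal SOs must live on frontal channels only")
            if so.so_type == "Local" and so.electrode_set.size > 0.2 * n:
                raise ValueError("Local SOs must cover <= 20% of channels")
            for e, d in zip(so.electrode_set, so.per_electrode_delay):
                per_electrode.setdefault(int(e), []).append(
                    (so.trough_time + d - so.duration / 2.0, so)
                )
        for e, entries in per_electrode.items():
            entries.sort(key=lambda t: t[0])
            for (s0, a), (s1, b) in zip(entries[:-1], entries[1:]):
                if s1 < s0 + a.span:
                    raise ValueError(
                        f"planted SOs overlap on electrode {e} "
                        f"(starts {s0:.2f} s and {s1:.2f} s)"
                    )


def so_waveform(rate: float, duration: float, trough_amplitude: float,
                up_duration: float, up_amplitude: float) -> np.ndarray:
    """Biphasic template: half-sine down state then half-sine up state."""
    n_down = max(2, int(round(duration * rate)))
    n_up = max(2, int(round(up_duration * rate)))
    down = trough_amplitude * np.sin(np.pi * np.arange(n_down) / n_down)
    up = up_amplitude * np.sin(np.pi * np.arange(n_up) / n_up)
    return np.concatenate([down, up])


def _one_over_f_noise(rng: np.random.Generator, shape, sigma: float,
                      rate: float) -> np.ndarray:
    white = rng.standard_normal(shape)
    F = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1], d=1.0 / rate)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    x = np.fft.irfft(F * scale, n=shape[-1], axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return sigma * x / sd


def generate_eeg(spec: SyntheticSpec) -> EegRecording:
    """Render the spec to an EEG recording (channels x samples, uV).

    Each planted SO contributes the biphasic template at its electrodes,
    shifted by its per-electrode delays and centred so the template trough
    lands at ``trough_time + delay``; Gaussian noise of SD ``noise_sigma``
    is superposed. The hypnogram follows the stage plan. Bit-identical for
    equal seeds.
    """
    rate = spec.sampling_rate
    n_samples = int(round(spec.total_duration * rate))
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        if spec.one_over_f:
            data = _one_over_f_noise(rng, (spec.n_channels, n_samples),
                                     spec.noise_sigma, rate)
        else:
            data = rng.normal(0.0, spec.noise_sigma, (spec.n_channels, n_samples))
    else:
        data = np.zeros((spec.n_channels, n_samples))

    for so in spec.so_plan:
        for e, d in zip(so.electrode_set, so.per_electrode_delay):
            # evaluate the continuous template at exact sample times, so the
            # planted trough is sub-sample aligned with trough_time + delay
            t0 = so.trough_time + d - so.duration / 2.0
            lo = max(0, int(np.floor(t0 * rate)))
            hi = min(n_samples, int(np.ceil((t0 + so.span) * rate)) + 1)
            if hi <= lo:
                continue
            tau = np.arange(lo, hi) / rate - t0
            down = (0 <= tau) & (tau < so.duration)
            up = (so.duration <= tau) & (tau <= so.span)
            wave = np.zeros(tau.size)
            wave[down] = so.trough_amplitude * np.sin(np.pi * tau[down] / so.duration)
            wave[up] = so.up_amplitude * np.sin(
                np.pi * (tau[up] - so.duration) / so.up_duration
            )
            data[e, lo:hi] += wave

    hypnogram = []
    for stage, dur in spec.stage_plan:
        hypnogram.extend([stage] * int(np.ceil(dur / EPOCH_SECONDS)))
    hypnogram = hypnogram[: int(np.ceil(n_samples / (EPOCH_SECONDS * rate)))]
    return EegRecording(
        data=data,
        sampling_rate=rate,
        channel_labels=list(spec.channel_labels),
        reference="synthetic common reference",
        hypnogram=np.array(hypnogram, dtype=object),
        participant=spec.participant,
    )


def random_so_plan(
    spec_or_channels,
    n_global: int,
    n_frontal: int,
    n_local: int,
    seed: int = 0,
    t_start: float = 5.0,
    t_end: float | None = None,
    spacing: float = 4.0,
    max_delay: float = 0.3,
    trough_amplitude: float = -100.0,
    duration: float = 0.5,
) -> list:
    """A non-overlapping plan of typed SOs at regularly jittered times.

    Global events cover all channels with random short delays, Frontal
    events the frontal row subset, Local events three scattered channels.
    Events are laid out ``spacing`` seconds apart (well beyond the
    co-detection window), in shuffled type order.
    """
    if isinstance(spec_or_channels, SyntheticSpec):
        labels = spec_or_channels.channel_labels
        t_end = t_end if t_end is not None else spec_or_channels.total_duration - 5.0
    else:
        labels = list(spec_or_channels)
        if t_end is None:
            raise ValueError("t_end required when passing bare channel labels")
    n_ch = len(labels)
    frontal_idx = np.flatnonzero(default_frontal_channels(labels))
    if frontal_idx.size == 0 and n_frontal > 0:
        raise ValueError("montage has no frontal channels")
    rng = np.random.default_rng(seed)
    types = (["Global"] * n_global + ["Frontal"] * n_frontal + ["Local"] * n_local)
    rng.shuffle(types)
    n_events = len(types)
    if t_start + n_events * spacing > t_end:
        raise ValueError("stage plan too short for the requested event count")
    plan = []
    for i, typ in enumerate(types):
        t = t_start + i * spacing + rng.uniform(0, spacing * 0.25)
        if typ == "Global":
            electrodes = np.arange(n_ch)
            delays = rng.uniform(-max_delay, max_delay, n_ch)
        elif typ == "Frontal":
            electrodes = frontal_idx
            delays = rng.uniform(-0.1, 0.1, electrodes.size)
        else:
            electrodes = rng.choice(n_ch, size=3, replace=False)
            delays = rng.uniform(-0.1, 0.1, 3)
        plan.append(
            PlantedSo(
                trough_time=t,
                so_type=typ,
                electrode_set=electrodes,
                per_electrode_delay=delays,
                trough_amplitude=trough_amplitude,
                duration=duration,
            )
        )
    return plan


#: Waveforms violating exactly one pre-filter detection criterion.
#: A >10-s duration decoy is not representable here: the 0.1 Hz high-pass
#: suppresses any stretch positive for longer than ~9 s, so the duration
#: criterion is exercised on constructed candidates instead.
DECOY_KINDS = ("amplitude", "p2p", "zc_short", "zc_long")


def decoy_waveform(kind: str, rate: float):
    """A decoy waveform and its trough offset (samples from waveform start).

    Kinds: ``amplitude`` (trough -70 uV), ``p2p`` (range 60 uV),
    ``zc_short`` (0.2-s down state), ``zc_long`` (1.2-s down state).
    """
    shapes = {
        "amplitude": (-70.0, 0.5, 35.0, 0.5),
        "p2p": (-50.0, 0.5, 10.0, 0.5),
        "zc_short": (-100.0, 0.2, 50.0, 0.2),
        "zc_long": (-100.0, 1.2, 50.0, 1.2),
    }
    if kind not in shapes:
        raise ValueError(f"unknown decoy kind {kind!r}; choose from {DECOY_KINDS}")
    trough_amp, duration, up_amp, up_duration = shapes[kind]
    wave = so_waveform(rate, duration, trough_amp, up_duration, up_amp)
    return wave, max(2, int(round(duration * rate))) // 2


def plant_decoys(data: np.ndarray, rate: float, plan) -> list:
    """Add decoy waveforms in place; ``plan`` is (time_s, channel, kind) triples.

    Returns the planted trough times.
    """
    troughs = []
    for t, ch, kind in plan:
        wave, off = decoy_waveform(kind, rate)
        start = int(round(t * rate)) - off
        if start < 0 or start + wave.size > data.shape[1]:
            raise ValueError(f"decoy at {t} s does not fit the recording")
        data[ch, start : start + wave.size] += wave
        troughs.append(t)
    return troughs


def save_planted_truth(spec: SyntheticSpec, path) -> None:
    """JSON sidecar with every planted event's ground truth."""
    payload = {
        "n_channels": spec.n_channels,
        "sampling_rate": spec.sampling_rate,
        "seed": spec.seed,
        "noise_sigma": spec.noise_sigma,
        "stage_plan": [[s, d] for s, d in spec.stage_plan],
        "planted": [
            {
                "trough_time": so.trough_time,
                "so_type": so.so_type,
                "electrode_set": so.electrode_set.tolist(),
                "per_electrode_delay": so.per_electrode_delay.tolist(),
                "trough_amplitude": so.trough_amplitude,
                "duration": so.duration,
                "up_amplitude": so.up_amplitude,
                "up_duration": so.up_duration,
            }
            for so in spec.so_plan
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# toy head model


@dataclass
class ToyHeadModel:
    """Analytic forward model: spherical sensors, 17 regional source blobs."""

    leadfield: np.ndarray          # (n_sensors, n_sources), uV per unit current
    source_positions: np.ndarray   # (n_sources, 3)
    sensor_positions: np.ndarray   # (n_sensors, 3)
    region_of_source: np.ndarray   # (n_sources,) ints indexing region_names
    region_names: list = field(default_factory=lambda: list(REGIONS))

    def __post_init__(self):
        self.leadfield = np.asarray(self.leadfield, dtype=float)
        self.region_of_source = np.asarray(self.region_of_source, dtype=int)
        present = np.unique(self.region_of_source)
        if not np.array_equal(present, np.arange(len(self.region_names))):
            raise ValueError("every region must have at least one source")

    @property
    def n_sensors(self) -> int:
        return self.leadfield.shape[0]

    @property
    def n_sources(self) -> int:
        return self.leadfield.shape[1]


def _fibonacci_sphere(n: int, radius: float = 1.0, hemisphere: bool = False) -> np.ndarray:
    i = np.arange(n) + 0.5
    if hemisphere:
        z = 1.0 - i / n          # upper hemisphere only
    else:
        z = 1.0 - 2.0 * i / n
    phi = np.pi * (1.0 + 5.0**0.5) * i
    r_xy = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return radius * np.column_stack([r_xy * np.cos(phi), r_xy * np.sin(phi), z])


def generate_head_model(
    n_sensors: int = 58,
    sources_per_region: int = 5,
    seed: int = 0,
    blob_sd: float = 0.04,
    eps: float = 0.05,
) -> ToyHeadModel:
    """Toy lead field with smooth distance-decay gain g = 1/(eps + r^2).

    Sensors sit on the upper unit hemisphere; the 17 region centres sit on
    an inner sphere (radius 0.55) with sources normally scattered around
    them (SD ``blob_sd``), keeping the blobs spatially disjoint. The
    resulting gain matrix has full sensor rank, which is verified.
    """
    if n_sensors < 4:
        raise ValueError("need at least 4 sensors")
    if sources_per_region < 1:
        raise ValueError("need at least one source per region")
    n_regions = len(REGIONS)
    n_sources = n_regions * sources_per_region
    if n_sources < n_sensors:
        raise ValueError(
            f"{n_sources} sources cannot give a rank-{n_sensors} lead field; "
            "increase sources_per_region"
        )
    rng = np.random.default_rng(seed)
    sensors = _fibonacci_sphere(n_sensors, radius=1.0, hemisphere=True)
    centres = _fibonacci_sphere(n_regions, radius=0.55)
    sources = np.repeat(centres, sources_per_region, axis=0)
    sources = sources + rng.normal(0.0, blob_sd, sources.shape)
    region_of_source = np.repeat(np.arange(n_regions), sources_per_region)

    diff = sensors[:, None, :] - sources[None, :, :]
    r2 = np.sum(diff**2, axis=-1)
    L = 1.0 / (eps + r2)
    if np.linalg.matrix_rank(L) < n_sensors:
        raise ValueError("toy lead field is sensor-rank deficient; change the seed")
    return ToyHeadModel(
        leadfield=L,
        source_positions=sources,
        sensor_positions=sensors,
        region_of_source=region_of_source,
        region_names=list(REGIONS),
    )


def project_sources(head: ToyHeadModel, source_currents: np.ndarray) -> np.ndarray:
    """Forward-project source currents to sensor voltages: V = L @ S."""
    S = np.atleast_2d(np.asarray(source_currents, dtype=float))
    if S.shape[0] != head.n_sources:
        raise ValueError("source_currents must be n_sources x n_times")
    return head.leadfield @ S


# ---------------------------------------------------------------------------
# labeled depth-profile datasets


def _resolve_features(effect_features) -> list:
    idx = []
    names = feature_names()
    for f in effect_features:
        if isinstance(f, (int, np.integer)):
            if not 0 <= f < len(names):
                raise ValueError(f"feature index {f} out of range")
            idx.append(int(f))
        elif isinstance(f, str):
            idx.append(names.index(f))
        else:
            region, bin_name = f
            idx.append(feature_index(region, bin_name))
    return idx


def generate_depth_dataset(
    n_global: int,
    n_nonglobal: int,
    effect_features,
    effect_size: float,
    seed: int = 0,
    baseline: float = 1.0,
    noise_sd: float = 0.2,
    stage: str = "S2",
    participant: str = "pooled",
) -> pd.DataFrame:
    """Labeled 51-feature depth profiles with a planted group difference.

    Non-Global rows are baseline noise, |N(baseline, noise_sd)| per feature;
    Global rows are shifted by ``effect_size * noise_sd`` on exactly the
    ``effect_features`` (region-bin pairs, feature names or flat indices).
    ``effect_size`` may be a scalar or one standardized shift per planted
    feature (graded selectivity). All values are magnitudes, hence
    non-negative.
    """
    idx = _resolve_features(effect_features)
    effect = np.broadcast_to(np.asarray(effect_size, dtype=float), (len(idx),))
    rng = np.random.default_rng(seed)
    names = feature_names()
    n = n_global + n_nonglobal
    X = rng.normal(baseline, noise_sd, (n, len(names)))
    X[:n_global, idx] += effect * noise_sd
    X = np.abs(X)
    df = pd.DataFrame(X, columns=names)
    df["participant"] = participant
    df["stage"] = stage
    df["is_global"] = np.arange(n) < n_global
    # shuffle row order so class blocks are not positional
    order = rng.permutation(n)
    return df.iloc[order].reset_index(drop=True)


def generate_depth_cohort(
    n_participants: int,
    n_global: int,
    n_nonglobal: int,
    effect_features,
    effect_size: float,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """A cohort of per-participant depth datasets (shared effect structure)."""
    root = np.random.default_rng(seed)
    frames = []
    for p in range(n_participants):
        frames.append(
            generate_depth_dataset(
                n_global, n_nonglobal, effect_features, effect_size,
                seed=int(root.integers(2**31)),
                participant=f"p{p + 1:02d}",
                **kwargs,
            )
        )
    return pd.concat(frames, ignore_index=True)
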