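"""Reading and writing sleep-EEG recordings, hypnograms and result tables.

The in-memory container is :class:`EegRecording`: a channels-by-samples
voltage array in microvolts plus a per-30-s-epoch hypnogram. Hypnograms are
plain text, one stage per 30-s epoch; both R&K numeric codes (0-5, with
stages 3 and 4 merging into SWS) and AASM-style string codes (W, N1-N3,
REM) are accepted. Recordings round-trip losslessly through an HDF5
container and, with 16-bit quantization, through EDF.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

EPOCH_SECONDS = 30.0

#: Canonical stage codes used throughout the package.
STAGES = ("W", "S1", "S2", "SWS", "REM")
ARTIFACT = "artifact"

# Accepted hypnogram dialects -> canonical codes. R&K stages 3 and 4 both
# denote slow-wave sleep.
_STAGE_ALIASES = {
    "0": "W", "w": "W", "wake": "W",
    "1": "S1", "s1": "S1", "n1": "S1",
    "2": "S2", "s2": "S2", "n2": "S2",
    "3": "SWS", "4": "SWS", "s3": "SWS", "s4": "SWS", "n3": "SWS",
    "sws": "SWS",
    "5": "REM", "r": "REM", "rem": "REM",
    "a": ARTIFACT, "-1": ARTIFACT, "artifact": ARTIFACT,
    "mvt": ARTIFACT,
}


class SleepIOError(ValueError):
    """Raised for malformed or inconsistent on-disk inputs."""


def normalize_stage(code) -> str:
    """Map a hypnogram stage code from any accepted dialect to canonical form."""
    key = str(code).strip().lower()
    if key in _STAGE_ALIASES:
        return _STAGE_ALIASES[key]
    if str(code).strip() in STAGES or str(code).strip() == ARTIFACT:
        return str(code).strip()
    raise SleepIOError(f"unknown sleep-stage code {code!r}")


@dataclass
class EegRecording:
    """Multichannel scalp EEG with its hypnogram.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltages in microvolts.
    sampling_rate : float
        Samples per second.
    channel_labels : list of str
        10-20 channel names, one per row of ``data``.
    channel_positions : ndarray, shape (n_channels, 3), optional
    reference : str
        Free-text descriptor of the recording reference.
    hypnogram : ndarray of str
        One canonical stage code per 30-s epoch.
    artifact_mask : ndarray of bool
        True marks an artifactual epoch (excluded when selections request
        artifact-free data). Defaults to all-False.
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: list
    channel_positions: np.ndarray | None = None
    reference: str = "unknown"
    hypnogram: np.ndarray = None
    artifact_mask: np.ndarray = None
    participant: str = "p01"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("one label per channel required")
        n_ep = self.n_epochs
        if self.hypnogram is None:
            self.hypnogram = np.array(["W"] * n_ep, dtype=object)
        self.hypnogram = np.array(
            [normalize_stage(s) for s in self.hypnogram], dtype=object
        )
        if len(self.hypnogram) != n_ep:
            raise SleepIOError(
                f"hypnogram length {len(self.hypnogram)} does not match "
                f"{n_ep} epochs ({self.n_samples} samples at "
                f"{self.sampling_rate} Hz, {EPOCH_SECONDS}-s epochs)"
            )
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(n_ep, dtype=bool)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if len(self.artifact_mask) != n_ep:
            raise SleepIOError("artifact_mask length must match epoch count")
        # epochs scored as artifact are artifactual by definition
        self.artifact_mask = self.artifact_mask | (self.hypnogram == ARTIFACT)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def n_epochs(self) -> int:
        return math.ceil(self.n_samples / (EPOCH_SECONDS * self.sampling_rate))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def epoch_of_sample(self, idx) -> np.ndarray:
        return (np.asarray(idx) // int(EPOCH_SECONDS * self.sampling_rate)).astype(int)


@dataclass
class StageSelection:
    """Which sleep stages (and artifact policy) an analysis runs on."""

    stages: frozenset = field(default_factory=lambda: frozenset({"S2", "SWS"}))
    artifact_free_only: bool = True

    def __post_init__(self):
        self.stages = frozenset(normalize_stage(s) for s in self.stages)
        if not self.stages:
            raise ValueError("stage selection must be non-empty")


def select_samples(rec: EegRecording, sel: StageSelection) -> np.ndarray:
    """Boolean per-sample mask, True on samples inside selected epochs.

    Epochs flagged in ``rec.artifact_mask`` are excluded when
    ``sel.artifact_free_only`` is set. An empty result triggers a warning.
    """
    epoch_ok = np.isin(rec.hypnogram, list(sel.stages))
    if sel.artifact_free_only:
        epoch_ok &= ~rec.artifact_mask
    samples_per_epoch = int(EPOCH_SECONDS * rec.sampling_rate)
    mask = np.repeat(epoch_ok, samples_per_epoch)[: rec.n_samples]
    if mask.size < rec.n_samples:  # last partial epoch
        pad = np.full(rec.n_samples - mask.size, epoch_ok[-1] if epoch_ok.size else False)
        mask = np.concatenate([mask, pad])
    if not mask.any():
        warnings.warn("stage selection matched no samples", stacklevel=2)
    return mask


# ---------------------------------------------------------------------------
# hypnogram text files


def read_hypnogram(path) -> np.ndarray:
    """Read a plain-text hypnogram, one stage code per line (or comma-separated)."""
    with open(path) as fh:
        text = fh.read()
    tokens = [t for t in text.replace(",", "\n").split() if t]
    if not tokens:
        raise SleepIOError(f"empty hypnogram file: {path}")
    bad = []
    stages = []
    for i, tok in enumerate(tokens):
        try:
            stages.append(normalize_stage(tok))
        except SleepIOError:
            bad.append((i, tok))
    if bad:
        raise SleepIOError(
            "unknown stage codes at epochs "
            + ", ".join(f"{i} ({t!r})" for i, t in bad)
        )
    return np.array(stages, dtype=object)


def write_hypnogram(stages, path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(str(s) for s in stages) + "\n")


# ---------------------------------------------------------------------------
# HDF5 container (lossless)


def save_recording(rec: EegRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.attrs["sampling_rate"] = rec.sampling_rate
        f.attrs["reference"] = rec.reference
        f.attrs["participant"] = rec.participant
        f.create_dataset(
            "channel_labels",
            data=np.array([str(c) for c in rec.channel_labels], dtype="S"),
        )
        if rec.channel_positions is not None:
            f.create_dataset("channel_positions", data=rec.channel_positions)
        f.create_dataset("hypnogram", data=np.array(rec.hypnogram, dtype="S"))
        f.create_dataset("artifact_mask", data=rec.artifact_mask)


def load_recording(path) -> EegRecording:
    try:
        with h5py.File(path, "r") as f:
            pos = f["channel_positions"][()] if "channel_positions" in f else None
            return EegRecording(
                data=f["data"][()],
                sampling_rate=float(f.attrs["sampling_rate"]),
                channel_labels=[c.decode() for c in f["channel_labels"][()]],
                channel_positions=pos,
                reference=str(f.attrs.get("reference", "unknown")),
                participant=str(f.attrs.get("participant", "p01")),
                hypnogram=np.array([s.decode() for s in f["hypnogram"][()]], dtype=object),
                artifact_mask=f["artifact_mask"][()],
            )
    except (OSError, KeyError) as exc:
        raise SleepIOError(f"cannot read recording container {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# EDF (16-bit)


def write_edf(rec: EegRecording, path) -> None:
    """Write a minimal EDF file (16-bit samples, 1-s data records).

    Physical range spans the per-channel data range; digital range is
    the full signed 16-bit span, so the quantization step is
    ``(phys_max - phys_min) / 65535`` microvolts.
    """
    rate = rec.sampling_rate
    if abs(rate - round(rate)) > 1e-9:
        raise SleepIOError("EDF export requires an integer sampling rate")
    spr = int(round(rate))  # samples per 1-s record
    n_rec = math.ceil(rec.n_samples / spr)
    n_pad = n_rec * spr - rec.n_samples
    data = rec.data
    if n_pad:
        data = np.pad(data, ((0, 0), (0, n_pad)), mode="edge")
    ns = rec.n_channels

    pmins = data.min(axis=1)
    pmaxs = data.max(axis=1)
    # degenerate flat channels still need a non-zero physical span
    flat = pmaxs - pmins < 1e-9
    pmaxs[flat] = pmins[flat] + 1.0
    dmin, dmax = -32768, 32767

    def pad(s, n):
        s = str(s)[:n]
        return s + " " * (n - len(s))

    header = b""
    header += pad("0", 8).encode()
    header += pad(rec.participant, 80).encode()
    header += pad("synthetic sleep EEG", 80).encode()
    header += pad("01.01.00", 8).encode() + pad("00.00.00", 8).encode()
    header += pad(str(256 * (ns + 1)), 8).encode()
    header += pad("", 44).encode()
    header += pad(str(n_rec), 8).encode()
    header += pad("1", 8).encode()  # record duration, s
    header += pad(str(ns), 4).encode()
    for lab in rec.channel_labels:
        header += pad(lab, 16).encode()
    header += b"".join(pad("AgAgCl electrode", 80).encode() for _ in range(ns))
    header += b"".join(pad("uV", 8).encode() for _ in range(ns))
    for v in pmins:
        header += pad(f"{v:.8g}"[:8], 8).encode()
    for v in pmaxs:
        header += pad(f"{v:.8g}"[:8], 8).encode()
    header += b"".join(pad(str(dmin), 8).encode() for _ in range(ns))
    header += b"".join(pad(str(dmax), 8).encode() for _ in range(ns))
    header += b"".join(pad("", 80).encode() for _ in range(ns))  # prefiltering
    header += b"".join(pad(str(spr), 8).encode() for _ in range(ns))
    header += b"".join(pad("", 32).encode() for _ in range(ns))

    # re-parse the truncated physical bounds so scaling matches what a
    # reader will see
    pmins_w = np.array([float(f"{v:.8g}"[:8]) for v in pmins])
    pmaxs_w = np.array([float(f"{v:.8g}"[:8]) for v in pmaxs])
    scale = (dmax - dmin) / (pmaxs_w - pmins_w)
    digital = np.rint((data - pmins_w[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            chunk = digital[:, r * spr : (r + 1) * spr]
            fh.write(chunk.tobytes())


def read_recording(path, hypnogram_path=None, artifact_path=None) -> EegRecording:
    """Read an EEG recording (EDF or HDF5 container) with optional hypnogram.

    Voltages are returned in microvolts regardless of the on-disk unit.
    """
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        rec = load_recording(path)
    elif path.endswith(".edf"):
        import mne

        try:
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        except Exception as exc:  # mne raises various types on truncation
            raise SleepIOError(f"cannot parse EDF file {path}: {exc}") from exc
        rec = EegRecording(
            data=raw.get_data() * 1e6,  # mne returns volts
            sampling_rate=float(raw.info["sfreq"]),
            channel_labels=list(raw.ch_names),
            reference="as recorded",
            hypnogram=["W"] * math.ceil(raw.n_times / (EPOCH_SECONDS * raw.info["sfreq"])),
        )
    else:
        raise SleepIOError(f"unrecognized recording format: {path}")
    if hypnogram_path is not None:
        hyp = read_hypnogram(hypnogram_path)
        if len(hyp) != rec.n_epochs:
            raise SleepIOError(
                f"hypnogram has {len(hyp)} epochs but recording has {rec.n_epochs}"
            )
        rec.hypnogram = hyp
        rec.artifact_mask = rec.artifact_mask | (hyp == ARTIFACT)
    if artifact_path is not None:
        mask = np.loadtxt(artifact_path, dtype=int).astype(bool)
        if mask.size != rec.n_epochs:
            raise SleepIOError("artifact mask length must match epoch count")
        rec.artifact_mask = rec.artifact_mask | mask
    return rec


# ---------------------------------------------------------------------------
# head models and tables


def save_head_model(head, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("leadfield", data=head.leadfield)
        f.create_dataset("source_positions", data=head.source_positions)
        f.create_dataset("sensor_positions", data=head.sensor_positions)
        f.create_dataset("region_of_source", data=head.region_of_source)
        f.create_dataset(
            "region_names", data=np.array(head.region_names, dtype="S")
        )


def load_head_model(path):
    from .synthetic_data import ToyHeadModel

    with h5py.File(path, "r") as f:
        return ToyHeadModel(
            leadfield=f["leadfield"][()],
            source_positions=f["source_positions"][()],
            sensor_positions=f["sensor_positions"][()],
            region_of_source=f["region_of_source"][()],
            region_names=[r.decode() for r in f["region_names"][()]],
        )


def save_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_profiles(df: pd.DataFrame, path) -> None:
    """Persist a depth-profile table (feature columns + label columns) to HDF5.

    Feature names are stored in a JSON header attribute.
    """
    from .depth_embedding import feature_names

    feats = [c for c in df.columns if c in set(feature_names())]
    labels = [c for c in df.columns if c not in feats]
    with h5py.File(path, "w") as f:
        f.create_dataset("profiles", data=df[feats].to_numpy(float))
        f.attrs["features"] = json.dumps(feats)
        for col in labels:
            f.create_dataset(
                f"labels/{col}", data=np.array(df[col].astype(str), dtype="S")
            )


def load_profiles(path) -> pd.DataFrame:
    with h5py.File(path, "r") as f:
        feats = json.loads(f.attrs["features"])
        df = pd.DataFrame(f["profiles"][()], columns=feats)
        if "labels" in f:
            for col in f["labels"]:
                vals = np.array([v.decode() for v in f[f"labels/{col}"][()]])
                if col == "is_global":
                    df[col] = vals == "True"
                else:
                    df[col] = vals
    return df
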