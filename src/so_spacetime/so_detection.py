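"""Per-electrode slow-oscillation detection.

The detector follows the classical scalp-EEG criteria for slow oscillations
(0.5-1.5 Hz NREM events): the signal is band-pass filtered at 0.1-4 Hz with
a zero-phase IIR filter, candidate events are delimited by consecutive
positive-to-negative and negative-to-positive zero crossings, and a
candidate becomes an event only if

1. its filtered trough is at or below -80 uV,
2. its peak-to-peak range is at least 80 uV,
3. the interval between its two zero crossings is 300 ms to 1 s, and
4. the whole candidate (down state plus following up state) lasts <= 10 s.

Accepted events then pass a two-stage amplitude screen: the trough
amplitude referenced to the local +/-10 s mean must not exceed the mean by
more than 4 SD, first within each electrode's own event distribution and
then within the pooled distribution of the stage-1 survivors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .sleep_io import EegRecording, StageSelection, select_samples


@dataclass
class DetectionParams:
    """Tunable detection thresholds (defaults are the standard criteria)."""

    band: tuple = (0.1, 4.0)          # Hz
    min_trough: float = -80.0         # uV, criterion 1 (trough <= min_trough)
    min_p2p: float = 80.0             # uV, criterion 2
    zc_interval: tuple = (0.3, 1.0)   # s, criterion 3
    max_duration: float = 10.0        # s, criterion 4
    artifact_sd: float = 4.0          # SD multiplier of the amplitude screen
    local_ref_window: float = 10.0    # s, half-width of the reference window
    filter_order: int = 4

    def __post_init__(self):
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError("band must satisfy 0 < low < high")
        if self.zc_interval[0] >= self.zc_interval[1]:
            raise ValueError("zc_interval must be increasing")
        for name in ("min_p2p", "max_duration", "artifact_sd", "local_ref_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SoEvent:
    """One detected slow oscillation at one electrode."""

    channel: str
    trough_time: float        # s
    pos2neg_zc: float         # s, first zero crossing
    neg2pos_zc: float         # s, second zero crossing
    trough_voltage: float     # uV, filtered signal
    peak_voltage: float       # uV, filtered signal
    peak_to_peak: float       # uV
    event_duration: float     # s, pos2neg crossing to next pos2neg crossing
    stage: str = "S2"
    participant: str = "p01"
    trough_index: int = -1
    local_ref_amplitude: float = float("nan")

    def validate(self) -> None:
        assert self.pos2neg_zc < self.trough_time < self.neg2pos_zc
        assert 0.3 <= self.neg2pos_zc - self.pos2neg_zc <= 1.0 + 1e-9
        assert self.event_duration <= 10.0 + 1e-9
        assert self.trough_voltage <= -80.0
        assert self.peak_to_peak >= 80.0


@dataclass
class Candidate:
    """A zero-crossing delimited span, before the acceptance criteria."""

    start: int      # sample of the pos->neg crossing
    zc2: int        # sample of the neg->pos crossing
    end: int        # sample of the next pos->neg crossing
    trough: int     # argmin between start and zc2
    peak: int       # argmax between zc2 and end


REJECT_CODES = ("min_trough", "min_p2p", "zc_interval", "max_duration")


def bandpass(x: np.ndarray, rate: float, params: DetectionParams | None = None) -> np.ndarray:
    """Zero-phase band-pass filter (forward-backward Butterworth)."""
    params = params or DetectionParams()
    if rate <= 2 * params.band[1]:
        raise ValueError("sampling rate must exceed twice the band's upper edge")
    sos = sps.butter(params.filter_order, params.band, btype="bandpass", fs=rate, output="sos")
    x = np.asarray(x, dtype=float)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.shape[-1] <= padlen:
        raise ValueError(
            f"signal length {x.shape[-1]} shorter than the filter transient ({padlen})"
        )
    return sps.sosfiltfilt(sos, x, axis=-1)


def find_candidates(filtered: np.ndarray, mask: np.ndarray | None = None) -> list:
    """List zero-crossing delimited candidate events in a filtered trace.

    Each candidate runs from a positive-to-negative zero crossing to the
    following negative-to-positive crossing (the down state); the trough is
    the minimum of that span and the peak the maximum up to the next
    positive-to-negative crossing. Candidates whose trough falls outside
    ``mask`` are dropped.
    """
    x = np.asarray(filtered, dtype=float)
    pos = x >= 0
    p2n = np.flatnonzero(pos[:-1] & ~pos[1:]) + 1   # first negative sample
    n2p = np.flatnonzero(~pos[:-1] & pos[1:]) + 1   # first non-negative sample
    out = []
    for i, start in enumerate(p2n[:-1]):
        nxt = n2p[np.searchsorted(n2p, start)] if np.searchsorted(n2p, start) < len(n2p) else None
        if nxt is None or nxt >= p2n[i + 1]:
            continue
        end = p2n[i + 1]
        trough = start + int(np.argmin(x[start:nxt]))
        peak = nxt + int(np.argmax(x[nxt:end]))
        if mask is not None and not mask[trough]:
            continue
        out.append(Candidate(start=int(start), zc2=int(nxt), end=int(end),
                             trough=trough, peak=peak))
    return out


def apply_criteria(
    cand: Candidate,
    filtered: np.ndarray,
    rate: float,
    params: DetectionParams | None = None,
    channel: str = "?",
    stage: str = "S2",
    participant: str = "p01",
):
    """Test one candidate against the four acceptance criteria.

    Returns ``(SoEvent, None)`` on acceptance or ``(None, code)`` where
    ``code`` names the first violated criterion.
    """
    params = params or DetectionParams()
    trough_v = float(filtered[cand.trough])
    peak_v = float(filtered[cand.peak])
    p2p = peak_v - trough_v
    zc_gap = (cand.zc2 - cand.start) / rate
    duration = (cand.end - cand.start) / rate
    if not trough_v <= params.min_trough:
        return None, "min_trough"
    if not p2p >= params.min_p2p:
        return None, "min_p2p"
    if not params.zc_interval[0] <= zc_gap <= params.zc_interval[1]:
        return None, "zc_interval"
    if not duration <= params.max_duration:
        return None, "max_duration"
    ev = SoEvent(
        channel=channel,
        trough_time=cand.trough / rate,
        pos2neg_zc=cand.start / rate,
        neg2pos_zc=cand.zc2 / rate,
        trough_voltage=trough_v,
        peak_voltage=peak_v,
        peak_to_peak=p2p,
        event_duration=duration,
        stage=stage,
        participant=participant,
        trough_index=cand.trough,
    )
    return ev, None


def detect_events(
    rec: EegRecording,
    params: DetectionParams | None = None,
    selection: StageSelection | None = None,
    reject: bool = True,
):
    """Full per-electrode detection on a recording.

    Runs band-pass filtering, candidate extraction and the four criteria on
    every channel independently, restricted to the selected (artifact-free)
    stage epochs, then optionally the two-stage 4-SD amplitude screen.
    Event stages are read from the epoch containing the trough.
    """
    params = params or DetectionParams()
    selection = selection or StageSelection()
    mask = select_samples(rec, selection)
    events = []
    for ci, label in enumerate(rec.channel_labels):
        filt = bandpass(rec.data[ci], rec.sampling_rate, params)
        for cand in find_candidates(filt, mask):
            ev, _ = apply_criteria(
                cand, filt, rec.sampling_rate, params,
                channel=label, participant=rec.participant,
            )
            if ev is not None:
                ev.stage = str(rec.hypnogram[rec.epoch_of_sample(cand.trough)])
                events.append(ev)
    if reject and events:
        events, _ = reject_artifacts(events, rec, params)
    return events


def local_reference_amplitude(ev: SoEvent, rec: EegRecording,
                              params: DetectionParams | None = None) -> float:
    """|trough - mean of the raw signal within +/-10 s of the trough|.

    The window is clipped at the recording edges rather than dropping the
    event.
    """
    params = params or DetectionParams()
    ci = list(rec.channel_labels).index(ev.channel)
    half = int(params.local_ref_window * rec.sampling_rate)
    i = ev.trough_index
    lo, hi = max(0, i - half), min(rec.n_samples, i + half + 1)
    ref = float(np.mean(rec.data[ci, lo:hi]))
    return abs(float(rec.data[ci, i]) - ref)


def reject_artifacts(events, rec: EegRecording, params: DetectionParams | None = None):
    """Two-stage 4-SD amplitude screen over trough amplitudes.

    Stage 1 builds, per electrode, the distribution of local-reference
    amplitudes of that electrode's events and discards events exceeding
    mean + 4 SD (electrodes with fewer than two events are skipped, the SD
    being undefined). Stage 2 pools the stage-1 survivors across all
    electrodes and discards above mean + 4 SD of the pooled distribution.

    Returns ``(survivors, info)`` where ``info`` counts removals per stage.
    """
    params = params or DetectionParams()
    if not events:
        raise ValueError("reject_artifacts requires at least one event")
    for ev in events:
        ev.local_ref_amplitude = local_reference_amplitude(ev, rec, params)

    by_channel: dict = {}
    for ev in events:
        by_channel.setdefault(ev.channel, []).append(ev)

    stage1 = []
    for chan, evs in by_channel.items():
        amps = np.array([e.local_ref_amplitude for e in evs])
        if len(evs) < 2:
            stage1.extend(evs)
            continue
        thr = amps.mean() + params.artifact_sd * amps.std(ddof=1)
        stage1.extend(e for e, a in zip(evs, amps) if a <= thr)

    amps = np.array([e.local_ref_amplitude for e in stage1])
    if len(stage1) >= 2:
        thr = amps.mean() + params.artifact_sd * amps.std(ddof=1)
        survivors = [e for e, a in zip(stage1, amps) if a <= thr]
    else:
        survivors = stage1
    info = {
        "n_input": len(events),
        "removed_stage1": len(events) - len(stage1),
        "removed_stage2": len(stage1) - len(survivors),
    }
    if not survivors:
        warnings.warn("artifact screening removed every event", stacklevel=2)
    return survivors, info


def events_to_table(events) -> pd.DataFrame:
    """Tabulate events (TSV-friendly)."""
    return pd.DataFrame(
        [
            {
                "participant": e.participant,
                "channel": e.channel,
                "stage": e.stage,
                "trough_time": e.trough_time,
                "pos2neg_zc": e.pos2neg_zc,
                "neg2pos_zc": e.neg2pos_zc,
                "trough_voltage": e.trough_voltage,
                "peak_to_peak": e.peak_to_peak,
                "event_duration": e.event_duration,
                "local_ref_amplitude": e.local_ref_amplitude,
            }
            for e in events
        ]
    )


def events_from_table(df: pd.DataFrame):
    """Rebuild SoEvent objects from a table written by :func:`events_to_table`."""
    events = []
    for row in df.itertuples(index=False):
        events.append(
            SoEvent(
                channel=row.channel,
                trough_time=row.trough_time,
                pos2neg_zc=row.pos2neg_zc,
                neg2pos_zc=row.neg2pos_zc,
                trough_voltage=row.trough_voltage,
                peak_voltage=row.trough_voltage + row.peak_to_peak,
                peak_to_peak=row.peak_to_peak,
                event_duration=row.event_duration,
                stage=row.stage,
                participant=str(row.participant),
                local_ref_amplitude=getattr(row, "local_ref_amplitude", float("nan")),
            )
        )
    return events
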