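"""Detection: filter response, candidates, criteria, amplitude screen."""

import numpy as np
import pytest

from so_spacetime import synthetic_data as syn
from so_spacetime.sleep_io import EegRecording, StageSelection
from so_spacetime.so_detection import (
    Candidate,
    apply_criteria,
    bandpass,
    detect_events,
    find_candidates,
    local_reference_amplitude,
    reject_artifacts,
)

RATE = 500.0


def _sine(freq, seconds=60.0, amp=1.0):
    t = np.arange(int(seconds * RATE)) / RATE
    return amp * np.sin(2 * np.pi * freq * t)


def test_bandpass_attenuates_out_of_band_and_passes_in_band():
    # steady-state amplitude measured away from the edges
    mid = slice(int(10 * RATE), int(50 * RATE))
    out10 = bandpass(_sine(10.0), RATE)
    assert np.abs(out10[mid]).max() < 0.1  # >= 20 dB down at 10 Hz
    out1 = bandpass(_sine(1.0), RATE)
    assert abs(np.abs(out1[mid]).max() - 1.0) < 0.05  # 1 Hz preserved


def test_bandpass_zero_phase_preserves_trough_timing():
    wave = syn.so_waveform(RATE, 0.5, -100.0, 0.5, 50.0)
    x = np.zeros(int(30 * RATE))
    x[int(10 * RATE) : int(10 * RATE) + wave.size] = wave
    f = bandpass(x, RATE)
    assert abs(np.argmin(f) - np.argmin(x)) <= 1


def test_bandpass_guards():
    with pytest.raises(ValueError, match="transient"):
        bandpass(np.zeros(10), RATE)
    with pytest.raises(ValueError, match="twice"):
        bandpass(np.zeros(1000), 6.0)


def test_single_planted_wave_yields_one_candidate_at_template_minimum():
    wave = syn.so_waveform(RATE, 0.6, -100.0, 0.6, 50.0)
    x = np.zeros(int(20 * RATE))
    start = int(8 * RATE)
    x[start : start + wave.size] = wave
    f = bandpass(x, RATE)
    cands = [c for c in find_candidates(f) if f[c.trough] < -50]
    assert len(cands) == 1
    assert abs(cands[0].trough - (start + np.argmin(wave))) <= 1


def test_constant_positive_signal_has_no_candidates():
    assert find_candidates(np.ones(1000)) == []


def test_two_planted_sos_give_two_candidates_in_time_order():
    wave = syn.so_waveform(RATE, 0.5, -100.0, 0.5, 50.0)
    x = np.zeros(int(30 * RATE))
    for t in (8.0, 13.0):
        s = int(t * RATE)
        x[s : s + wave.size] = wave
    f = bandpass(x, RATE)
    cands = [c for c in find_candidates(f) if f[c.trough] < -50]
    assert len(cands) == 2
    assert cands[0].trough < cands[1].trough


def test_mask_drops_candidates_with_trough_outside():
    wave = syn.so_waveform(RATE, 0.5, -100.0, 0.5, 50.0)
    x = np.zeros(int(20 * RATE))
    s = int(8 * RATE)
    x[s : s + wave.size] = wave
    f = bandpass(x, RATE)
    mask = np.zeros(x.size, dtype=bool)  # everything masked out
    assert [c for c in find_candidates(f, mask) if f[c.trough] < -50] == []


def _make_candidate(trough_v, peak_v, zc_gap, duration, rate=RATE):
    """Construct a synthetic filtered trace realizing the given candidate."""
    n = int((duration + 2.0) * rate)
    f = np.full(n, 1e-6)
    start = int(0.5 * rate)
    zc2 = start + int(zc_gap * rate)
    end = start + int(duration * rate)
    trough = (start + zc2) // 2
    peak = (zc2 + end) // 2
    f[start:zc2] = -1e-6
    f[trough] = trough_v
    f[peak] = peak_v
    return Candidate(start=start, zc2=zc2, end=end, trough=trough, peak=peak), f


@pytest.mark.parametrize(
    "trough_v, peak_v, zc_gap, duration, expected",
    [
        (-100.0, 50.0, 0.6, 1.2, None),            # satisfies all criteria
        (-80.0, 10.0, 0.5, 1.0, None),             # boundary: exactly -80, p2p 90
        (-70.0, 80.0, 0.6, 1.2, "min_trough"),
        (-85.0, -10.0, 0.6, 1.2, "min_p2p"),       # p2p 75 < 80
        (-100.0, 50.0, 0.25, 1.2, "zc_interval"),
        (-100.0, 50.0, 1.1, 2.0, "zc_interval"),
        (-100.0, 50.0, 0.6, 12.0, "max_duration"), # 12-s candidate span
    ],
)
def test_criteria_accept_and_first_violation_reason(trough_v, peak_v, zc_gap,
                                                    duration, expected):
    cand, f = _make_candidate(trough_v, peak_v, zc_gap, duration)
    ev, reason = apply_criteria(cand, f, RATE)
    assert reason == expected
    if expected is None:
        assert ev is not None
        ev.validate()
        assert ev.pos2neg_zc < ev.trough_time < ev.neg2pos_zc


def test_detection_recovers_planted_sos_only_in_selected_stage():
    spec = syn.SyntheticSpec(noise_sigma=0.0, seed=0,
                             stage_plan=[("S2", 60.0), ("W", 60.0)])
    n = spec.n_channels
    mk = lambda t: syn.PlantedSo(trough_time=t, so_type="Global",
                                 electrode_set=np.arange(n))
    spec.so_plan = [mk(30.0), mk(90.0)]  # second lands in Wake
    spec.validate_plan()
    rec = syn.generate_eeg(spec)
    events = detect_events(rec, selection=StageSelection(stages={"S2"}))
    assert len(events) == n
    assert all(abs(e.trough_time - 30.0) < 0.05 for e in events)
    assert all(e.stage == "S2" for e in events)


def test_channel_permutation_permutes_events():
    spec = syn.SyntheticSpec(noise_sigma=0.0, seed=0, n_channels=6,
                             stage_plan=[("S2", 60.0)])
    spec.so_plan = [syn.PlantedSo(trough_time=30.0, so_type="Local",
                                  electrode_set=np.array([1]))]
    rec = syn.generate_eeg(spec)
    perm = [5, 4, 3, 2, 1, 0]
    rec_p = EegRecording(
        data=rec.data[perm],
        sampling_rate=rec.sampling_rate,
        channel_labels=[rec.channel_labels[i] for i in perm],
        hypnogram=rec.hypnogram,
    )
    ev = detect_events(rec, reject=False)
    ev_p = detect_events(rec_p, reject=False)
    assert {(e.channel, round(e.trough_time, 3)) for e in ev} == \
           {(e.channel, round(e.trough_time, 3)) for e in ev_p}


# -- amplitude screen -------------------------------------------------------


def _events_with_amplitudes(amps, rate=100.0, channel_of=None):
    """One recording whose raw samples realize given trough amplitudes."""
    n_ev = len(amps)
    n_ch = max(channel_of) + 1 if channel_of else 1
    n = int((n_ev + 2) * 60 * rate)
    data = np.zeros((n_ch, n))
    events = []
    from so_spacetime.so_detection import SoEvent

    for i, a in enumerate(amps):
        ch = channel_of[i] if channel_of else 0
        idx = int((i + 1) * 60 * rate)
        data[ch, idx] = -a  # trough sample; window mean ~ 0
        events.append(SoEvent(
            channel=f"C{ch}", trough_time=idx / rate,
            pos2neg_zc=idx / rate - 0.3, neg2pos_zc=idx / rate + 0.3,
            trough_voltage=-max(a, 80.0), peak_voltage=10.0,
            peak_to_peak=max(a, 80.0) + 10.0, event_duration=1.0,
            trough_index=idx,
        ))
    n_epochs = int(np.ceil(n / (30 * rate)))
    rec = EegRecording(data=data, sampling_rate=rate,
                       channel_labels=[f"C{i}" for i in range(n_ch)],
                       hypnogram=np.array(["S2"] * n_epochs, dtype=object))
    return events, rec


def test_equal_amplitudes_all_survive():
    events, rec = _events_with_amplitudes([100.0] * 50)
    survivors, info = reject_artifacts(events, rec)
    assert len(survivors) == 50
    assert info["removed_stage1"] == info["removed_stage2"] == 0


def test_single_outlier_discarded_at_stage1():
    amps = [100.0] * 99 + [10000.0]
    events, rec = _events_with_amplitudes(amps)
    # independent oracle: explicit mean + 4 sd of the 100-value set
    arr = np.array([e.local_ref_amplitude for e in events]) if False else None
    vals = np.array(amps, dtype=float)
    thr = vals.mean() + 4 * vals.std(ddof=1)
    assert vals.max() > thr > 100.0
    survivors, info = reject_artifacts(events, rec)
    assert len(survivors) == 99
    assert info["removed_stage1"] == 1
    assert all(e.local_ref_amplitude < 200 for e in survivors)


def test_stage1_skipped_for_single_event_electrode_stage2_still_pools():
    # electrode 1 has a single extreme event: stage 1 cannot screen it
    # (sd undefined) but the pooled stage-2 screen removes it
    amps = [100.0] * 60 + [10000.0]
    channel_of = [0] * 60 + [1]
    events, rec = _events_with_amplitudes(amps, channel_of=channel_of)
    survivors, info = reject_artifacts(events, rec)
    assert info["removed_stage1"] == 0
    assert info["removed_stage2"] == 1
    assert len(survivors) == 60


def test_reference_window_clipped_at_recording_edge():
    rate = 100.0
    n = int(60 * rate)
    data = np.zeros((1, n))
    data[0, 50] = -120.0
    from so_spacetime.so_detection import SoEvent

    ev = SoEvent(channel="C0", trough_time=0.5, pos2neg_zc=0.2, neg2pos_zc=0.8,
                 trough_voltage=-120.0, peak_voltage=10.0, peak_to_peak=130.0,
                 event_duration=1.0, trough_index=50)
    rec = EegRecording(data=data, sampling_rate=rate, channel_labels=["C0"],
                       hypnogram=np.array(["S2"] * 2, dtype=object))
    amp = local_reference_amplitude(ev, rec)  # trough 0.5 s from the edge
    assert np.isfinite(amp) and amp > 100.0


def test_reject_artifacts_requires_events():
    events, rec = _events_with_amplitudes([100.0])
    with pytest.raises(ValueError, match="at least one"):
        reject_artifacts([], rec)
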