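"""Filtering, envelope, threshold detection and array grouping."""

import numpy as np
import pytest
from scipy import signal

from ripplemap.swr import (ArrayRippleEvent, RippleEvent, bandpass_ripple,
                           detect_channel_events, group_array_events,
                           ripple_envelope)

FS = 1250.0


# ----------------------------------------------------------------------
# band-pass
# ----------------------------------------------------------------------

def test_inband_tone_passes_with_zero_lag_and_unit_gain():
    t = np.arange(0, 2, 1 / FS)
    x = np.sin(2 * np.pi * 150 * t)
    y = bandpass_ripple(x, FS)
    mid = slice(200, -200)
    # gain ~ 1 in the passband center
    assert np.std(y[mid]) == pytest.approx(np.std(x[mid]), rel=0.02)
    # zero-phase: cross-correlation peak at lag 0
    c = signal.correlate(y[mid], x[mid], mode="full")
    lags = signal.correlation_lags(len(y[mid]), len(x[mid]))
    assert lags[np.argmax(c)] == 0


def test_out_of_band_attenuation_matches_transfer_function_oracle():
    """Forward+reverse filtering attenuates |H|^2; check vs sosfreqz."""
    t = np.arange(0, 4, 1 / FS)
    x = np.sin(2 * np.pi * 50 * t)
    y = bandpass_ripple(x, FS)
    atten_db = 20 * np.log10(np.std(y[500:-500]) / np.std(x[500:-500]))
    assert atten_db <= -20.0
    sos = signal.butter(4, [120, 250], btype="bandpass", fs=FS, output="sos")
    _, h = signal.sosfreqz(sos, worN=[50], fs=FS)
    oracle_db = 20 * np.log10(np.abs(h[0]) ** 2)    # squared: two passes
    assert atten_db == pytest.approx(oracle_db, abs=1.5)


def test_dc_offset_removed():
    x = np.full(4000, 7.5)
    y = bandpass_ripple(x, FS)
    assert np.abs(y[100:-100]).max() < 1e-6


def test_band_above_nyquist_rejected():
    with pytest.raises(ValueError, match="Nyquist"):
        bandpass_ripple(np.zeros(100), 400.0, band=(120, 250))


# ----------------------------------------------------------------------
# envelope
# ----------------------------------------------------------------------

def test_envelope_of_unit_tone_is_one():
    t = np.arange(0, 2, 1 / FS)
    env = ripple_envelope(np.sin(2 * np.pi * 150 * t))
    assert np.allclose(env[200:-200], 1.0, atol=0.01)


def test_envelope_tracks_amplitude_modulation():
    t = np.arange(0, 2, 1 / FS)
    am = 1 + 0.5 * np.sin(2 * np.pi * 5 * t)
    env = ripple_envelope(am * np.sin(2 * np.pi * 150 * t))
    rmse = np.sqrt(np.mean((env[200:-200] - am[200:-200]) ** 2))
    assert rmse < 0.02


def test_envelope_bounds_signal_and_zeros_map_to_zeros():
    rng = np.random.default_rng(0)
    x = rng.normal(size=2000)
    env = ripple_envelope(x)
    assert np.all(env >= np.abs(x) - 1e-9)
    assert np.allclose(ripple_envelope(np.zeros(500)), 0.0)


def test_envelope_rejects_non_finite():
    with pytest.raises(ValueError, match="finite"):
        ripple_envelope(np.array([0.0, np.nan, 1.0]))


# ----------------------------------------------------------------------
# channel event detection
# ----------------------------------------------------------------------

def _toy_envelope(bumps, n=12500, base=1.0, width_ms=30.0):
    """Baseline-1 envelope with Gaussian bumps ((time_s, height), ...)."""
    t = np.arange(n) / FS
    env = np.full(n, base)
    for t0, h in bumps:
        env += h * np.exp(-((t - t0) ** 2) / (2 * (width_ms / 1000 / 2) ** 2))
    return env


def _brute_force_detect(env, fs, thresh_sd, merge_gap_ms, min_dur_ms):
    """Independent scan oracle: literal per-sample walk of the rules."""
    m, s = env.mean(), env.std()
    thr = m + thresh_sd * s
    # candidate = each suprathreshold run, extended to the mean crossings
    cands = []
    i = 0
    n = len(env)
    while i < n:
        if env[i] > thr:
            lo = i
            while lo > 0 and env[lo - 1] > m:
                lo -= 1
            hi = i
            while hi < n and env[hi] > m:
                hi += 1
            cands.append((lo, hi))
            i = hi
        else:
            i += 1
    # deduplicate, merge by gap iteratively, then duration-filter
    cands = sorted(set(cands))
    gap = merge_gap_ms / 1000 * fs
    done = False
    while not done:
        done = True
        out = []
        for c in cands:
            if out and c[0] - out[-1][1] < gap:
                out[-1] = (out[-1][0], max(out[-1][1], c[1]))
                done = False
            else:
                out.append(c)
        cands = out
    return [(lo, hi) for lo, hi in cands if hi - lo >= min_dur_ms / 1000 * fs]


def test_close_crossings_merge_into_one_event():
    """Two suprathreshold bumps separated by an 8 ms subthreshold gap fuse."""
    env = _toy_envelope([(5.0, 20.0), (5.05, 20.0)], width_ms=12)
    # bumps this close share a return-to-mean interval or an 8 ms gap
    evs = detect_channel_events(env, FS)[0]
    assert len(evs) == 1


def test_short_isolated_bump_discarded():
    env = _toy_envelope([(5.0, 30.0)], width_ms=4)   # ~15 ms above the mean
    evs15 = detect_channel_events(env, FS, min_dur_ms=20.0)[0]
    evs5 = detect_channel_events(env, FS, min_dur_ms=5.0)[0]
    assert evs15 == [] and len(evs5) == 1


def test_randomized_envelopes_match_brute_force_oracle():
    rng = np.random.default_rng(3)
    for _ in range(20):
        n_bumps = rng.integers(1, 8)
        bumps = [(rng.uniform(0.5, 9.5), rng.uniform(5, 40))
                 for _ in range(n_bumps)]
        env = _toy_envelope(bumps, width_ms=rng.uniform(5, 40))
        env += rng.normal(0, 0.02, size=len(env))
        got = detect_channel_events(env, FS)[0]
        want = _brute_force_detect(env, FS, 4.5, 10.0, 20.0)
        assert [(round(e.t_start * FS), round(e.t_end * FS)) for e in got] \
            == [(a, b) for a, b in want]


def test_flat_envelope_warns_and_yields_nothing():
    with pytest.warns(UserWarning, match="flat"):
        evs = detect_channel_events(np.ones(1000), FS)
    assert evs == [[]]


def test_event_count_monotone_in_threshold():
    rng = np.random.default_rng(4)
    env = _toy_envelope([(rng.uniform(1, 9), rng.uniform(5, 30))
                         for _ in range(6)])
    env += rng.normal(0, 0.05, len(env))
    counts = [len(detect_channel_events(env, FS, thresh_sd=k)[0])
              for k in (2.0, 3.0, 4.5, 6.0, 8.0)]
    assert counts == sorted(counts, reverse=True)


def test_detection_invariant_under_polarity_flip():
    rng = np.random.default_rng(5)
    lfp = rng.normal(size=(1, 8000))
    t = np.arange(8000) / FS
    lfp[0] += 10 * np.exp(-((t - 3) ** 2) / (2 * 0.02**2)) * np.cos(
        2 * np.pi * 150 * t)
    env_pos = ripple_envelope(bandpass_ripple(lfp, FS))
    env_neg = ripple_envelope(bandpass_ripple(-lfp, FS))
    ev_pos = detect_channel_events(env_pos, FS)[0]
    ev_neg = detect_channel_events(env_neg, FS)[0]
    assert [(e.t_start, e.t_end) for e in ev_pos] \
        == [(e.t_start, e.t_end) for e in ev_neg]


# ----------------------------------------------------------------------
# array grouping
# ----------------------------------------------------------------------

def _ev(ch, a, b):
    return RippleEvent(channel_id=ch, t_start=a, t_end=b,
                       t_peak=(a + b) / 2, peak_z=5.0)


def test_identical_event_on_all_channels_groups_once():
    evs = [[_ev(c, 1.0, 1.06)] for c in range(16)]
    arr = group_array_events(evs)
    assert len(arr) == 1 and len(arr[0].members) == 16
    assert arr[0].t_start == 1.0 and arr[0].t_end == 1.06


def test_distant_events_stay_separate():
    evs = [[_ev(0, 1.0, 1.05)], [_ev(1, 1.10, 1.15)]]
    assert len(group_array_events(evs)) == 2


def test_transitive_chain_becomes_single_event():
    """A-B overlap and B-C overlap while A and C are disjoint."""
    evs = [[_ev(0, 1.00, 1.04)], [_ev(1, 1.03, 1.08)], [_ev(2, 1.07, 1.12)]]
    arr = group_array_events(evs)
    assert len(arr) == 1
    assert arr[0].t_start == 1.00 and arr[0].t_end == 1.12
    # independent check: interval-graph transitive closure via networkx
    import networkx as nx
    g = nx.Graph()
    flat = [e for evs_ in evs for e in evs_]
    g.add_nodes_from(range(len(flat)))
    for i in range(len(flat)):
        for j in range(i + 1, len(flat)):
            a, b = flat[i], flat[j]
            gap = max(a.t_start, b.t_start) - min(a.t_end, b.t_end)
            if gap < 0.010:
                g.add_edge(i, j)
    assert nx.number_connected_components(g) == len(arr)


def test_array_event_bounds_follow_earliest_start_latest_end():
    evs = [[_ev(0, 1.00, 1.03)], [_ev(5, 0.98, 1.02)], [_ev(9, 1.02, 1.09)]]
    arr = group_array_events(evs)
    assert len(arr) == 1
    assert arr[0].t_start == 0.98 and arr[0].t_end == 1.09
    assert arr[0].channels == [0, 5, 9]
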