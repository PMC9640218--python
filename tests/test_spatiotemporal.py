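"""Delay mapping, envelope screening, features, clustering, wave speed."""

import numpy as np
import pytest

from ripplemap.io import ChannelGeometry
from ripplemap.swr import ArrayRippleEvent, RippleEvent
from ripplemap.spatiotemporal import (build_features, channel_delays,
                                      classify_group, cluster_events,
                                      complete_delays, dtw_distance,
                                      envelope_shape_screen, estimate_wave_speed,
                                      gaussian_template)

FS = 1250.0
GEOM = ChannelGeometry.grid()


def _array_event(t0=1.0, t1=1.1):
    m = RippleEvent(0, t0, t1, (t0 + t1) / 2, 5.0)
    return ArrayRippleEvent(event_id=0, t_start=t0, t_end=t1,
                            t_peak=(t0 + t1) / 2, members=[m])


def _envelopes(delays_ms, n=int(3 * FS), t0=1.5, sigma=0.02, noise=0.0,
               seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(n) / FS
    env = np.vstack([np.exp(-((t - t0 - d / 1000) ** 2) / (2 * sigma**2))
                     for d in delays_ms])
    if noise:
        env += rng.normal(0, noise, size=env.shape)
    return env


# ----------------------------------------------------------------------
# delays
# ----------------------------------------------------------------------

def test_identical_envelopes_give_zero_delay_all_valid():
    env = _envelopes(np.zeros(16))
    delays, valid = channel_delays(_array_event(1.4, 1.6), env, FS)
    assert valid.all()
    assert np.allclose(delays, 0.0, atol=1e-6)


def test_planted_linear_ramp_recovered_within_one_sample():
    planted = np.linspace(0, 8, 16)
    env = _envelopes(planted, noise=0.01)
    delays, valid = channel_delays(_array_event(1.4, 1.6), env, FS)
    assert valid.all()
    rec = delays - delays.mean()
    want = planted - planted.mean()
    assert np.max(np.abs(rec - want)) <= 1000.0 / FS


def test_pure_noise_channel_marked_invalid():
    env = _envelopes(np.zeros(16), noise=0.0)
    rng = np.random.default_rng(1)
    env[7] = rng.normal(0, 0.3, size=env.shape[1])
    delays, valid = channel_delays(_array_event(1.4, 1.6), env, FS)
    assert not valid[7]
    assert valid.sum() == 15
    assert np.isnan(delays[7])


def test_window_beyond_recording_bounds_skips_event():
    env = _envelopes(np.zeros(16))
    with pytest.warns(UserWarning, match="bounds"):
        out = channel_delays(_array_event(0.0, 0.02), env, FS)
    assert out is None


# ----------------------------------------------------------------------
# interpolation
# ----------------------------------------------------------------------

def _plane_delays(a=0.004, b=0.002):
    return GEOM.positions @ np.array([a, b])   # ms, linear in position


def test_fewer_than_13_valid_channels_discards_event():
    d = _plane_delays()
    mask = np.ones(16, bool)
    mask[:4] = False   # 12 valid
    assert complete_delays(d, mask, GEOM) is None


def test_all_valid_passes_through_unchanged():
    d = _plane_delays()
    out = complete_delays(d, np.ones(16, bool), GEOM)
    assert np.array_equal(out, d)


@pytest.mark.parametrize("missing", [[5], [0], [0, 15, 6], [3, 12]])
def test_plane_wave_interpolation_error_below_half_ms(missing):
    d = _plane_delays()
    mask = np.ones(16, bool)
    mask[missing] = False
    out = complete_delays(d, mask, GEOM)
    assert np.max(np.abs(out[missing] - d[missing])) <= 0.5


# ----------------------------------------------------------------------
# DTW screen
# ----------------------------------------------------------------------

def test_dtw_distance_zero_for_identical_series():
    x = gaussian_template(64)
    assert dtw_distance(x, x) == 0.0


def test_gaussian_envelopes_retained_two_peak_discarded():
    # 5% contamination: outliers beyond mean + 3.5 SD of the distance pool
    rng = np.random.default_rng(2)
    t = np.linspace(-3, 3, 120)
    envs = [np.exp(-t**2 / 2) + rng.normal(0, 0.02, len(t))
            for _ in range(57)]
    for _ in range(3):
        envs.append(np.exp(-(t + 1.5) ** 2 / 0.5)
                    + np.exp(-(t - 1.5) ** 2 / 0.5)
                    + rng.normal(0, 0.02, len(t)))
    keep, dist = envelope_shape_screen(envs)
    assert not keep[57:].any()
    assert keep[:57].sum() >= 55


def test_identical_envelopes_degenerate_sd_keeps_all():
    envs = [gaussian_template(64)] * 12
    keep, _ = envelope_shape_screen(envs)
    assert keep.all()


def test_too_few_events_skips_screen_with_warning():
    envs = [gaussian_template(64)] * 4
    with pytest.warns(UserWarning, match="skipped"):
        keep, _ = envelope_shape_screen(envs)
    assert keep.all()


# ----------------------------------------------------------------------
# features
# ----------------------------------------------------------------------

def test_single_hot_channel_power_pattern():
    delays = np.zeros((1, 16))
    powers = np.full((1, 16), 0.05)
    powers[0, 3] = 5.0
    delays2 = np.random.default_rng(0).normal(0, 2, size=(1, 16))
    feats, pn = build_features(np.vstack([delays, delays2]),
                               np.vstack([powers, powers]))
    assert pn[0, 3] == 1.0
    assert np.all(pn[0, np.arange(16) != 3] < 0.05)


def test_feature_blocks_share_pooled_sd_and_scaling_is_idempotent():
    rng = np.random.default_rng(3)
    delays = rng.normal(0, 3, size=(40, 16))
    powers = rng.uniform(0.01, 1, size=(40, 16))
    feats, pn = build_features(delays, powers)
    d_block, p_block = feats[:, :16], feats[:, 16:]
    assert d_block.std() == pytest.approx(p_block.std(), abs=1e-9)
    feats2, _ = build_features(d_block, p_block)
    assert np.allclose(feats2, feats, atol=1e-12)


def test_features_match_independent_two_pass_recomputation():
    rng = np.random.default_rng(4)
    delays = rng.normal(0, 3, size=(25, 16))
    powers = rng.uniform(0.01, 2, size=(25, 16))
    feats, _ = build_features(delays, powers)
    # oracle: explicit two-pass normalization written out longhand
    pn = powers / powers.max(axis=1)[:, None]
    want = np.hstack([delays / delays.std(), pn / pn.std()])
    assert np.allclose(feats, want, atol=1e-12)


def test_zero_power_event_rejected():
    with pytest.raises(ValueError, match="zero-power"):
        build_features(np.zeros((1, 16)), np.zeros((1, 16)))


# ----------------------------------------------------------------------
# group classification
# ----------------------------------------------------------------------

@pytest.mark.parametrize("span,n_active,want", [
    (6.0, 12, "global-traveling"),
    (0.0, 4, "local-stationary"),
    (5.0, 10, "local-stationary"),   # boundaries are strict inequalities
    (5.001, 11, "global-traveling"),
    (6.0, 4, "local-traveling"),
    (0.0, 12, "global-stationary"),
])
def test_group_rules(span, n_active, want):
    delays = np.zeros(16)
    delays[0] = span
    powers = np.full(16, 0.05)
    powers[:n_active] = 0.9
    assert classify_group(delays, powers) == want


def test_group_invariant_to_delay_offset():
    rng = np.random.default_rng(5)
    delays = rng.normal(0, 2, 16)
    powers = rng.uniform(0, 1, 16)
    a = classify_group(delays, powers)
    b = classify_group(delays + 123.4, powers)
    assert a == b


# ----------------------------------------------------------------------
# clustering
# ----------------------------------------------------------------------

def _blob_features(rng, n_per=30):
    centers = rng.normal(0, 5, size=(4, 32))
    feats = np.vstack([c + rng.normal(0, 0.3, size=(n_per, 32))
                       for c in centers])
    labels = np.repeat(np.arange(4), n_per)
    return feats, labels


def test_kmeans_elbow_finds_four_blobs_and_is_deterministic():
    rng = np.random.default_rng(6)
    feats, labels = _blob_features(rng)
    delays = feats[:, :16]
    powers = np.abs(feats[:, 16:]) / np.abs(feats[:, 16:]).max(axis=1)[:, None]
    m1 = cluster_events(feats, delays, powers, seed=3)
    m2 = cluster_events(feats, delays, powers, seed=3)
    assert m1.k == 4
    assert np.array_equal(m1.assignments, m2.assignments)
    from sklearn.metrics import adjusted_rand_score
    assert adjusted_rand_score(labels, m1.assignments) == 1.0


def test_duplicate_rows_collapse_to_single_cluster_with_warning():
    feats = np.tile(np.arange(32, dtype=float), (30, 1))
    with pytest.warns(UserWarning, match="identical"):
        m = cluster_events(feats, feats[:, :16], np.ones((30, 16)), seed=0)
    assert m.k == 1
    assert np.all(m.assignments == 0)


# ----------------------------------------------------------------------
# wave speed
# ----------------------------------------------------------------------

def test_plane_wave_speed_and_direction_recovered_exactly():
    # 0.15 m/s = 150 um/ms along +x: delay = x / 150 ms
    d = GEOM.positions[:, 0] / 150.0
    speed, direction = estimate_wave_speed(d, GEOM)
    assert speed == pytest.approx(0.15, rel=1e-9)
    assert np.allclose(direction, [1.0, 0.0], atol=1e-9)


def test_rotated_wave_rotates_direction_keeps_speed():
    d = GEOM.positions[:, 1] / 150.0       # propagate along +y
    speed, direction = estimate_wave_speed(d, GEOM)
    assert speed == pytest.approx(0.15, rel=1e-9)
    assert np.allclose(direction, [0.0, 1.0], atol=1e-9)


def test_flat_delay_map_reports_stationary_sentinel():
    speed, direction = estimate_wave_speed(np.full(16, 2.5), GEOM)
    assert np.isinf(speed) and direction is None


def test_collinear_channels_rejected():
    geom = ChannelGeometry(np.column_stack([np.arange(4) * 500.0,
                                            np.zeros(4)]))
    with pytest.raises(ValueError, match="collinear"):
        estimate_wave_speed(np.arange(4, dtype=float), geom)
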