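"""Spatiotemporal characterization and clustering of array-level ripples.

For each array event the per-channel envelope delay (cross-correlation against
the grid-mean envelope, with a 0.5 correlation validity rule and a 13-channel
minimum) and the normalized ripple-band power form a 32-dimensional feature
vector.  Events whose peak-channel envelope deviates from a single Gaussian
peak (dynamic-time-warping screen at mean + 3.5 SD of the distance population)
are discarded.  K-means with an elbow rule over k and 10 seeded restarts
yields ripple clusters, which are mapped to the four spatiotemporal groups —
{local, global} x {stationary, traveling} — by strict threshold rules on the
cluster templates: traveling iff the template delay span exceeds 5 ms, global
iff strictly more than 10 channels have normalized power above 0.6.

A least-squares plane fit on a delay map provides traveling-wave speed and
direction (used for the theta traveling wave; the fitting choice is ours, see
the methods note).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.interpolate import griddata
from sklearn.cluster import KMeans

from .config import RunConfig
from .io import ChannelGeometry
from .swr import ArrayRippleEvent, bandpass_ripple

__all__ = [
    "SWRFeatureVector",
    "SWRClusterModel",
    "channel_delays",
    "complete_delays",
    "dtw_distance",
    "envelope_shape_screen",
    "build_features",
    "cluster_events",
    "classify_group",
    "estimate_wave_speed",
    "theta_delays",
    "extract_event_features",
]

GROUPS = ("local-stationary", "local-traveling",
          "global-stationary", "global-traveling")


@dataclass
class SWRFeatureVector:
    event_id: int
    delays_ms: np.ndarray         # (n_channels,), relative to the mean envelope
    powers_norm: np.ndarray       # (n_channels,), max = 1 for retained events
    valid_mask: np.ndarray        # (n_channels,) bool
    dtw_distance: float = np.nan


@dataclass
class SWRClusterModel:
    k: int
    templates_scaled: np.ndarray      # (k, 2 * n_channels) in feature space
    templates_delay_ms: np.ndarray    # (k, n_channels) raw-space templates
    templates_power: np.ndarray       # (k, n_channels)
    assignments: np.ndarray           # cluster index per retained event
    group_labels: list[str]           # per cluster, one of GROUPS
    inertia_by_k: dict[int, float] = field(default_factory=dict)

    def group_of_events(self) -> np.ndarray:
        return np.asarray([self.group_labels[c] for c in self.assignments])


# ----------------------------------------------------------------------
# delays
# ----------------------------------------------------------------------

def _norm_xcorr_delay(x: np.ndarray, y: np.ndarray, fs: float,
                      max_lag_ms: float) -> tuple[float, float]:
    """Delay of ``x`` relative to ``y`` (positive = x later), subsample-refined.

    Uses the normalized cross-correlation of the mean-centered signals,
    restricted to lags within ``max_lag_ms``; the peak is refined by parabolic
    interpolation.  Returns ``(delay_ms, peak_correlation)``.
    """
    # subtract the baseline *floor* (median), not the mean: envelopes are
    # non-negative bumps on a noise floor, and mean-centering leaves both
    # series with nonzero plateaus whose product adds a triangular term
    # (peaked at lag 0) that biases the argmax toward zero delay
    xc = x - np.median(x)
    yc = y - np.median(y)
    denom = np.linalg.norm(xc) * np.linalg.norm(yc)
    if denom == 0:
        return 0.0, 0.0
    c = signal.correlate(xc, yc, mode="full") / denom
    lags = signal.correlation_lags(len(xc), len(yc), mode="full")
    max_lag = int(round(max_lag_ms / 1000.0 * fs))
    sel = np.abs(lags) <= max_lag
    c, lags = c[sel], lags[sel]
    i = int(np.argmax(c))
    peak = float(c[i])
    lag = float(lags[i])
    if 0 < i < len(c) - 1:
        denom2 = c[i - 1] - 2 * c[i] + c[i + 1]
        if denom2 < 0:
            lag += 0.5 * (c[i - 1] - c[i + 1]) / denom2
    return lag / fs * 1000.0, peak


def _shift(x: np.ndarray, shift_samples: float) -> np.ndarray:
    """Shift a series by a (fractional) number of samples via interpolation."""
    idx = np.arange(len(x)) + shift_samples
    return np.interp(idx, np.arange(len(x)), x)


def channel_delays(event: ArrayRippleEvent, envelopes: np.ndarray, fs: float,
                   xcorr_min: float = 0.5, pad_ms: float = 50.0,
                   max_lag_ms: float = 20.0, n_iter: int = 3
                   ) -> tuple[np.ndarray, np.ndarray] | None:
    """Per-channel envelope delays relative to the 16-channel mean envelope.

    The event interval is padded symmetrically by ``pad_ms``; channels whose
    peak normalized cross-correlation with the mean envelope falls below
    ``xcorr_min`` are marked invalid.

    Correlating against the raw mean envelope of a traveling event biases the
    delays toward zero (the unaligned mean is a temporally blurred template),
    so the template is refined iteratively: after each pass the channels are
    re-aligned by their current delay estimates and the mean recomputed.  A
    few iterations remove the compression for delay spans well below the
    envelope width.  Returns ``(delays_ms, valid_mask)`` or ``None`` when the
    padded window exceeds the recording bounds.
    """
    n = envelopes.shape[1]
    pad = int(round(pad_ms / 1000.0 * fs))
    i0 = int(round(event.t_start * fs)) - pad
    i1 = int(round(event.t_end * fs)) + pad
    if i0 < 0 or i1 > n:
        warnings.warn(f"event {event.event_id} window exceeds recording bounds; "
                      "skipped")
        return None
    win = envelopes[:, i0:i1]
    n_ch = win.shape[0]
    delays = np.zeros(n_ch)
    valid = np.ones(n_ch, dtype=bool)
    for it in range(max(n_iter, 1)):
        if valid.any():
            aligned = np.vstack([_shift(win[c], delays[c] / 1000.0 * fs)
                                 if valid[c] else win[c]
                                 for c in range(n_ch)])
            mean_env = aligned[valid].mean(axis=0)
        else:
            mean_env = win.mean(axis=0)
        for c in range(n_ch):
            d, peak = _norm_xcorr_delay(win[c], mean_env, fs, max_lag_ms)
            delays[c] = d
            valid[c] = peak >= xcorr_min
    delays = np.where(valid, delays, np.nan)
    return delays, valid


def _plane_fit(points: np.ndarray, values: np.ndarray) -> np.ndarray:
    A = np.column_stack([points, np.ones(len(points))])
    coef, *_ = np.linalg.lstsq(A, values, rcond=None)
    return coef


def complete_delays(delays_ms: np.ndarray, valid_mask: np.ndarray,
                    geometry: ChannelGeometry,
                    min_valid: int = 13) -> np.ndarray | None:
    """Fill invalid channel delays by 2D interpolation, or discard the event.

    Events with fewer than ``min_valid`` valid channels return ``None``
    (discard).  Missing delays inside the convex hull of valid channels are
    filled by barycentric linear interpolation; points outside the hull (grid
    corners) are filled from a least-squares plane fit, which is exact for
    plane-wave delay maps.
    """
    valid_mask = np.asarray(valid_mask, dtype=bool)
    if valid_mask.sum() < min_valid:
        return None
    out = np.array(delays_ms, dtype=float)
    if valid_mask.all():
        return out
    pts = geometry.positions
    filled = griddata(pts[valid_mask], out[valid_mask], pts[~valid_mask],
                      method="linear")
    coef = _plane_fit(pts[valid_mask], out[valid_mask])
    nan = ~np.isfinite(filled)
    if nan.any():
        miss = pts[~valid_mask][nan]
        filled[nan] = miss @ coef[:2] + coef[2]
    out[~valid_mask] = filled
    return out


# ----------------------------------------------------------------------
# envelope shape screen (DTW)
# ----------------------------------------------------------------------

def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Classic dynamic-time-warping distance with absolute-difference cost,
    normalized by the warped path length upper bound (len(a) + len(b))."""
    n, m = len(a), len(b)
    cost = np.abs(a[:, None] - b[None, :])
    dp = np.full((n + 1, m + 1), np.inf)
    dp[0, 0] = 0.0
    for i in range(1, n + 1):
        row = dp[i]
        prev = dp[i - 1]
        ci = cost[i - 1]
        for j in range(1, m + 1):
            row[j] = ci[j - 1] + min(prev[j], row[j - 1], prev[j - 1])
    return float(dp[n, m] / (n + m))


def _normalize_envelope(env: np.ndarray, n_points: int = 64) -> np.ndarray:
    """Length- and amplitude-normalize an envelope segment (unit max)."""
    x = np.interp(np.linspace(0, 1, n_points),
                  np.linspace(0, 1, len(env)), env)
    mx = x.max()
    return x / mx if mx > 0 else x


def gaussian_template(n_points: int = 64) -> np.ndarray:
    """Unit-amplitude Gaussian, sigma = length / 6, matching the envelope grid."""
    i = np.arange(n_points)
    c = (n_points - 1) / 2.0
    s = n_points / 6.0
    return np.exp(-((i - c) ** 2) / (2 * s * s))


def envelope_shape_screen(peak_envelopes: list[np.ndarray],
                          dtw_sd: float = 3.5, n_points: int = 64,
                          min_events: int = 10
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Screen events for single-peaked (Gaussian-like) envelope shape.

    Each event's peak-channel envelope is length/amplitude-normalized and
    compared to a unit Gaussian template by DTW; events whose distance exceeds
    mean + ``dtw_sd`` SD of the population of distances are discarded.  With
    fewer than ``min_events`` events the screen is skipped (all retained).

    Returns ``(keep_mask, distances)``.
    """
    tpl = gaussian_template(n_points)
    d = np.array([dtw_distance(_normalize_envelope(e, n_points), tpl)
                  for e in peak_envelopes])
    if len(d) < min_events:
        warnings.warn(f"only {len(d)} events; DTW envelope screen skipped")
        return np.ones(len(d), dtype=bool), d
    sd = d.std()
    if sd == 0:
        return np.ones(len(d), dtype=bool), d
    thr = d.mean() + dtw_sd * sd
    return d <= thr, d


# ----------------------------------------------------------------------
# features
# ----------------------------------------------------------------------

def build_features(delays_ms: np.ndarray, powers: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Assemble per-event feature vectors [delay block | power block].

    ``powers`` holds the per-channel mean squared ripple-band signal in the
    event window; it is normalized per event by the maximal channel.  The
    delay block and the power block are each rescaled to unit pooled standard
    deviation across events, so both carry equal weight in clustering (the
    operation is idempotent).  Returns ``(features, powers_norm)``.
    """
    delays_ms = np.atleast_2d(np.asarray(delays_ms, dtype=float))
    powers = np.atleast_2d(np.asarray(powers, dtype=float))
    pmax = powers.max(axis=1, keepdims=True)
    if np.any(pmax <= 0):
        raise ValueError("zero-power event in feature assembly")
    powers_norm = powers / pmax
    sd_d = delays_ms.std()
    sd_p = powers_norm.std()
    d_block = delays_ms / sd_d if sd_d > 0 else delays_ms
    p_block = powers_norm / sd_p if sd_p > 0 else powers_norm
    return np.hstack([d_block, p_block]), powers_norm


def event_band_power(filtered: np.ndarray, event: ArrayRippleEvent,
                     fs: float) -> np.ndarray:
    """Mean squared ripple-band signal per channel over the event window."""
    i0 = max(int(round(event.t_start * fs)), 0)
    i1 = min(int(round(event.t_end * fs)), filtered.shape[1])
    return (filtered[:, i0:i1] ** 2).mean(axis=1)


# ----------------------------------------------------------------------
# clustering + group rules
# ----------------------------------------------------------------------

def classify_group(delay_template_ms: np.ndarray, power_template: np.ndarray,
                   travel_ms: float = 5.0, power_active: float = 0.6,
                   global_min_channels: int = 10) -> str:
    """Map a cluster template to one of the four spatiotemporal groups.

    Traveling iff the delay span (max - min) strictly exceeds ``travel_ms``;
    global iff the number of channels with normalized power strictly above
    ``power_active`` strictly exceeds ``global_min_channels``.  Boundary
    values (span exactly 5 ms, exactly 10 active channels) are therefore
    stationary / local.
    """
    span = float(np.max(delay_template_ms) - np.min(delay_template_ms))
    temporal = "traveling" if span > travel_ms else "stationary"
    n_active = int(np.sum(np.asarray(power_template) > power_active))
    spatial = "global" if n_active > global_min_channels else "local"
    return f"{spatial}-{temporal}"


def _elbow_k(inertia_by_k: dict[int, float]) -> int:
    ks = sorted(inertia_by_k)
    if len(ks) < 3:
        return ks[0]
    inertia = np.array([inertia_by_k[k] for k in ks])
    # maximum discrete curvature of the inertia-vs-k curve
    d2 = inertia[:-2] - 2 * inertia[1:-1] + inertia[2:]
    return ks[1 + int(np.argmax(d2))]


def cluster_events(features: np.ndarray,
                   delays_ms: np.ndarray, powers_norm: np.ndarray,
                   k_range: tuple[int, int] = (2, 10),
                   n_restarts: int = 10, seed: int = 0,
                   config: RunConfig | None = None) -> SWRClusterModel:
    """K-means over k in ``k_range`` with best-of-``n_restarts`` by inertia.

    k is chosen at the elbow (maximum curvature) of the inertia curve;
    restarts are seeded ``seed + 0 .. n_restarts - 1`` with ties broken by the
    lowest seed.  Raw-space templates (mean delay / power per cluster) feed
    :func:`classify_group`.
    """
    cfg = config or RunConfig()
    n_events = features.shape[0]
    ks = [k for k in range(k_range[0], k_range[1] + 1) if k <= n_events]
    if not ks:
        raise ValueError("not enough events to cluster")
    if np.allclose(features, features[0]):
        warnings.warn("all feature vectors identical; single trivial cluster")
        return SWRClusterModel(
            k=1, templates_scaled=features[:1].copy(),
            templates_delay_ms=delays_ms[:1].copy(),
            templates_power=powers_norm[:1].copy(),
            assignments=np.zeros(n_events, dtype=int),
            group_labels=[classify_group(delays_ms[0], powers_norm[0],
                                         cfg.travel_ms, cfg.power_active,
                                         cfg.global_min_channels)],
            inertia_by_k={1: 0.0})

    best_models: dict[int, KMeans] = {}
    inertia_by_k: dict[int, float] = {}
    for k in ks:
        best = None
        for r in range(n_restarts):
            km = KMeans(n_clusters=k, n_init=1, random_state=seed + r,
                        algorithm="lloyd").fit(features)
            if best is None or km.inertia_ < best.inertia_:
                best = km
        best_models[k] = best
        inertia_by_k[k] = float(best.inertia_)
    k_star = _elbow_k(inertia_by_k)
    model = best_models[k_star]
    assign = model.labels_.astype(int)
    tpl_d = np.vstack([delays_ms[assign == c].mean(axis=0)
                       for c in range(k_star)])
    tpl_p = np.vstack([powers_norm[assign == c].mean(axis=0)
                       for c in range(k_star)])
    labels = [classify_group(tpl_d[c], tpl_p[c], cfg.travel_ms,
                             cfg.power_active, cfg.global_min_channels)
              for c in range(k_star)]
    return SWRClusterModel(k=k_star, templates_scaled=model.cluster_centers_,
                           templates_delay_ms=tpl_d, templates_power=tpl_p,
                           assignments=assign, group_labels=labels,
                           inertia_by_k=inertia_by_k)


# ----------------------------------------------------------------------
# traveling-wave speed
# ----------------------------------------------------------------------

def estimate_wave_speed(delays_ms: np.ndarray, geometry: ChannelGeometry,
                        stationary_tol_ms_per_um: float = 1e-6
                        ) -> tuple[float, np.ndarray | None]:
    """Plane-fit wave speed from a per-channel delay map.

    Fits ``delay(x, y) = a x + b y + c`` by least squares; the speed is
    ``1 / |(a, b)|`` converted to m/s and the direction is the unit gradient
    (direction of propagation).  A flat delay map returns ``(inf, None)`` —
    the stationary sentinel.  Collinear channel layouts are rejected.
    """
    pts = geometry.positions
    delays_ms = np.asarray(delays_ms, dtype=float)
    ok = np.isfinite(delays_ms)
    pts, d = pts[ok], delays_ms[ok]
    if len(d) < 3:
        raise ValueError("need at least 3 channels with delays")
    A = np.column_stack([pts, np.ones(len(pts))])
    if np.linalg.matrix_rank(A) < 3:
        raise ValueError("channel positions are collinear; plane fit undefined")
    coef = _plane_fit(pts, d)
    g = float(np.hypot(coef[0], coef[1]))     # ms per um
    if g < stationary_tol_ms_per_um:
        return np.inf, None
    speed_m_s = 1e-3 / g                      # um/ms -> m/s
    direction = np.array([coef[0], coef[1]]) / g
    return speed_m_s, direction


def theta_delays(lfp: np.ndarray, fs: float,
                 band: tuple[float, float] = (4.0, 8.0),
                 mask: np.ndarray | None = None,
                 order: int = 4) -> np.ndarray:
    """Per-channel theta phase lag (ms) relative to the grid-mean phase.

    The band-passed analytic phase of each channel is compared to the circular
    mean phase across channels; the circular mean of the per-sample phase
    offsets (over ``mask``, e.g. running epochs) divided by the measured
    instantaneous frequency gives the lag.  Positive = later.
    """
    filt = bandpass_ripple(lfp, fs, band, order)
    analytic = signal.hilbert(filt, axis=-1)
    unit = analytic / np.maximum(np.abs(analytic), 1e-30)
    ref = unit.mean(axis=0)
    ref /= np.maximum(np.abs(ref), 1e-30)
    rel = unit * np.conj(ref)[None, :]
    if mask is not None:
        rel = rel[:, mask]
        phase_ref = np.unwrap(np.angle(ref))[mask]
    else:
        phase_ref = np.unwrap(np.angle(ref))
    dphi = np.angle(rel.mean(axis=1))
    freq = np.median(np.diff(phase_ref)) * fs / (2 * np.pi)
    # a channel lagging the reference accumulates a *negative* phase offset
    return -dphi / (2 * np.pi * freq) * 1000.0


# ----------------------------------------------------------------------
# end-to-end feature extraction
# ----------------------------------------------------------------------

def extract_event_features(array_events: list[ArrayRippleEvent],
                           filtered: np.ndarray, envelopes: np.ndarray,
                           fs: float, geometry: ChannelGeometry,
                           config: RunConfig | None = None
                           ) -> tuple[list[SWRFeatureVector], np.ndarray,
                                      np.ndarray, np.ndarray, list[int]]:
    """Delays + powers + DTW screen for a list of array events.

    Returns ``(feature_vectors, features, delays_ms, powers_norm,
    kept_event_ids)`` where ``features`` is the scaled (events x 2C) matrix of
    the retained events.
    """
    cfg = config or RunConfig()
    fvs: list[SWRFeatureVector] = []
    kept_events: list[ArrayRippleEvent] = []
    for ev in array_events:
        res = channel_delays(ev, envelopes, fs, cfg.xcorr_min,
                             cfg.delay_pad_ms, cfg.max_lag_ms)
        if res is None:
            continue
        delays, valid = res
        full = complete_delays(delays, valid, geometry, cfg.min_valid_channels)
        if full is None:
            continue
        full = full - full[valid].mean()   # delays relative to the mean envelope
        fvs.append(SWRFeatureVector(event_id=ev.event_id, delays_ms=full,
                                    powers_norm=np.empty(0), valid_mask=valid))
        kept_events.append(ev)
    if not fvs:
        return [], np.empty((0, 0)), np.empty((0, 0)), np.empty((0, 0)), []

    # DTW screen on the peak-power channel envelope of each surviving event
    peak_envs = []
    powers = []
    for ev in kept_events:
        p = event_band_power(filtered, ev, fs)
        powers.append(p)
        c = int(np.argmax(p))
        i0 = int(round(ev.t_start * fs))
        i1 = int(round(ev.t_end * fs))
        peak_envs.append(envelopes[c, i0:i1])
    keep, dists = envelope_shape_screen([e for e in peak_envs], cfg.dtw_sd)
    for fv, dist in zip(fvs, dists):
        fv.dtw_distance = float(dist)
    fvs = [fv for fv, k in zip(fvs, keep) if k]
    kept_events = [ev for ev, k in zip(kept_events, keep) if k]
    powers = [p for p, k in zip(powers, keep) if k]
    if not fvs:
        return [], np.empty((0, 0)), np.empty((0, 0)), np.empty((0, 0)), []

    delays_mat = np.vstack([fv.delays_ms for fv in fvs])
    powers_mat = np.vstack(powers)
    features, powers_norm = build_features(delays_mat, powers_mat)
    for fv, pn in zip(fvs, powers_norm):
        fv.powers_norm = pn
    kept_ids = [ev.event_id for ev in kept_events]
    return fvs, features, delays_mat, powers_norm, kept_ids
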