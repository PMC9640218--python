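"""Spike-LFP relations: ripple-triggered rates, phase locking, calcium match.

Phase convention: the instantaneous phase is the angle of the analytic signal
of the ripple-band LFP, so phase 0 falls at the signal maximum (cosine
convention) and the rising zero-crossing is at -pi/2.  The phase-locking
value (PLV) is the magnitude of the mean unit phasor over spikes; by default
each channel's PLV uses only the spikes inside that channel's ripple
intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PhaseLockResult",
    "swr_triggered_rate",
    "ripple_phase_at_spikes",
    "plv",
    "rayleigh_test",
    "plv_map",
    "plv_null_threshold",
    "mua_calcium_match",
]


@dataclass
class PhaseLockResult:
    cluster_id: str
    channel_id: int
    plv: float
    preferred_phase: float     # radians in (-pi, pi]
    p_rayleigh: float
    n_spikes: int
    low_n: bool


# ----------------------------------------------------------------------

def swr_triggered_rate(spike_times: np.ndarray, swr_onsets: np.ndarray,
                       window_s: float = 0.5, bin_ms: float = 10.0
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Event-triggered firing-rate histogram (PSTH) in Hz.

    Spikes are binned relative to each onset over ``+-window_s`` and averaged
    across events; the SEM is computed over events.  Returns
    ``(bin_centers_s, rate_hz, sem_hz)``.
    """
    onsets = np.asarray(swr_onsets, dtype=float)
    if len(onsets) == 0:
        raise ValueError("no events for the triggered rate")
    sp = np.sort(np.asarray(spike_times, dtype=float))
    bin_s = bin_ms / 1000.0
    edges = np.arange(-window_s, window_s + bin_s / 2, bin_s)
    centers = 0.5 * (edges[:-1] + edges[1:])
    per_event = np.empty((len(onsets), len(centers)))
    for i, on in enumerate(onsets):
        lo = np.searchsorted(sp, on - window_s)
        hi = np.searchsorted(sp, on + window_s)
        per_event[i] = np.histogram(sp[lo:hi] - on, bins=edges)[0]
    rate = per_event.mean(axis=0) / bin_s
    sem = per_event.std(axis=0, ddof=1) / np.sqrt(len(onsets)) / bin_s \
        if len(onsets) > 1 else np.zeros_like(rate)
    return centers, rate, sem


def ripple_phase_at_spikes(filtered: np.ndarray, fs: float,
                           spike_times: np.ndarray,
                           t0: float = 0.0) -> np.ndarray:
    """Instantaneous ripple-band phase at each spike time.

    The unwrapped analytic phase is linearly interpolated at the spike times
    and re-wrapped to (-pi, pi].  Spikes outside the LFP span are dropped
    (count logged as a warning).
    """
    x = np.asarray(filtered, dtype=float)
    phase = np.unwrap(np.angle(signal.hilbert(x)))
    sp = np.asarray(spike_times, dtype=float)
    idx = (sp - t0) * fs
    ok = (idx >= 0) & (idx <= len(x) - 1)
    if (~ok).sum():
        warnings.warn(f"{int((~ok).sum())} spike(s) outside the LFP span "
                      "dropped")
    vals = np.interp(idx[ok], np.arange(len(x)), phase)
    return np.angle(np.exp(1j * vals))


def plv(phases: np.ndarray) -> tuple[float, float]:
    """Phase-locking value and preferred phase of a phase sample."""
    if len(phases) == 0:
        return np.nan, np.nan
    z = np.exp(1j * np.asarray(phases)).mean()
    return float(np.abs(z)), float(np.angle(z))


def rayleigh_test(phases: np.ndarray) -> float:
    """Rayleigh test p-value for non-uniformity of circular data."""
    n = len(phases)
    if n == 0:
        return np.nan
    r, _ = plv(phases)
    z = n * r * r
    # Zar's small-sample-corrected approximation
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n * n - (n * r) ** 2)) - (1 + 2 * n))
    return float(min(max(p, 0.0), 1.0))


def _spikes_in_intervals(sp: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    """Mask of spikes falling in any of the (n, 2) half-open intervals."""
    if len(intervals) == 0:
        return np.zeros(len(sp), dtype=bool)
    bounds = np.sort(np.asarray(intervals, dtype=float), axis=0).ravel()
    return np.searchsorted(bounds, sp, side="right") % 2 == 1


def plv_map(spike_times: np.ndarray, filtered_lfp: np.ndarray, fs: float,
            intervals_per_channel: list[np.ndarray],
            cluster_id: str = "", t0: float = 0.0,
            low_n: int = 20,
            restrict_to_swr: bool = True) -> list[PhaseLockResult]:
    """Per-channel PLV of a spike cluster against each channel's ripples.

    For every channel the spikes inside that channel's ripple intervals (or
    all spikes when ``restrict_to_swr`` is off) contribute a phase sample from
    that channel's ripple-band signal.  Channels with fewer than ``low_n``
    spikes are flagged.
    """
    sp = np.sort(np.asarray(spike_times, dtype=float))
    out = []
    for c in range(filtered_lfp.shape[0]):
        if restrict_to_swr:
            mask = _spikes_in_intervals(sp, intervals_per_channel[c])
            sel = sp[mask]
        else:
            sel = sp
        phases = ripple_phase_at_spikes(filtered_lfp[c], fs, sel, t0)
        r, mu = plv(phases)
        out.append(PhaseLockResult(
            cluster_id=cluster_id, channel_id=c, plv=r, preferred_phase=mu,
            p_rayleigh=rayleigh_test(phases), n_spikes=len(phases),
            low_n=len(phases) < low_n))
    return out


def plv_null_threshold(n_spikes: int, pct: float = 99.0,
                       n_resamples: int = 1000,
                       seed: int | np.random.Generator = 0) -> float:
    """``pct`` percentile of the PLV of ``n_spikes`` uniform phases."""
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    ph = rng.uniform(-np.pi, np.pi, size=(n_resamples, n_spikes))
    r = np.abs(np.exp(1j * ph).mean(axis=1))
    return float(np.percentile(r, pct))


# ----------------------------------------------------------------------

def mua_calcium_match(spike_times: np.ndarray,
                      transient_intervals_per_cell: list[np.ndarray],
                      cell_xy: np.ndarray, electrode_xy: np.ndarray,
                      duration_s: float, radius_um: float = 100.0,
                      n_shuffle: int = 10000,
                      seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Match MUA spikes to calcium transients of cells near the electrode.

    For each cell within ``radius_um`` of the electrode, the number of spikes
    overlapping its calcium-transient intervals is compared to a null built by
    circularly shifting the spike train by ``n_shuffle`` uniform offsets
    (preserving inter-spike structure).  One-sided p-values are BH-corrected
    across the cells tested.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    sp = np.asarray(spike_times, dtype=float)
    d = np.hypot(*(np.asarray(cell_xy, dtype=float)
                   - np.asarray(electrode_xy, dtype=float)).T)
    near = np.flatnonzero(d <= radius_um)
    if len(near) == 0:
        warnings.warn("no cells within the matching radius")
        return pd.DataFrame(columns=["cell", "dist_um", "n_overlap",
                                     "null_mean", "p", "p_fdr"])
    offsets = rng.uniform(0, duration_s, size=n_shuffle)
    shifted = (sp[None, :] + offsets[:, None]) % duration_s
    rows = []
    for cell in near:
        ivals = np.asarray(transient_intervals_per_cell[cell], dtype=float)
        obs = int(_spikes_in_intervals(sp, ivals).sum())
        if len(ivals) == 0:
            null_counts = np.zeros(n_shuffle)
        else:
            bounds = np.sort(ivals, axis=0).ravel()
            inside = np.searchsorted(bounds, shifted, side="right") % 2 == 1
            null_counts = inside.sum(axis=1)
        p = (1 + int((null_counts >= obs).sum())) / (n_shuffle + 1)
        rows.append({"cell": int(cell), "dist_um": float(d[cell]),
                     "n_overlap": obs,
                     "null_mean": float(null_counts.mean()), "p": p})
    df = pd.DataFrame(rows)
    df["p_fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
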