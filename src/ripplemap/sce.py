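"""Synchronous calcium events (SCEs) and their co-occurrence with ripples.

dF/F traces are deconvolved to a non-negative activity signal, thresholded at
3 SD above each cell's mean to give per-cell firing intervals, and the number
of cells firing within the adjacent 5 imaging frames (~160 ms at 30 Hz) is
counted per frame.  The chance level is calibrated by circularly shuffling
each cell's firing intervals 20 times and pooling the counts; the 95th
percentile of the pooled null is the SCE threshold.  Ripple/SCE co-occurrence
uses a +-200 ms window, with significance from 1000 random redraws of the
ripple times (restricted to immobility when a state mask is available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d

__all__ = [
    "FiringRaster",
    "SCEEvent",
    "deconvolve",
    "firing_raster",
    "transient_intervals",
    "coactivity_counts",
    "sce_threshold",
    "detect_sce",
    "cooccurrence",
    "cooccurrence_significance",
]


@dataclass
class FiringRaster:
    raster: np.ndarray          # (cells, frames) bool
    thresholds: np.ndarray      # per-cell activity threshold used
    fs_img: float


@dataclass
class SCEEvent:
    frame: int
    t: float
    n_coactive: int
    cells: np.ndarray


# ----------------------------------------------------------------------

def deconvolve(dff: np.ndarray, fs_img: float = 30.0,
               tau_s: float = 0.4) -> np.ndarray:
    """Non-negative exponential-kernel deconvolution of dF/F.

    Inverts a first-order (AR(1)) calcium kernel with decay ``tau_s``:
    ``a[t] = max(0, f[t] - phi f[t-1])`` with ``phi = exp(-1 / (fs tau))``.
    An impulse-kernel transient maps to a single dominant activity peak at its
    onset.  Precomputed activity may be passed straight to
    :func:`firing_raster` instead.
    """
    f = np.atleast_2d(np.asarray(dff, dtype=float))
    if not np.isfinite(f).all():
        raise ValueError("dff contains non-finite values")
    phi = np.exp(-1.0 / (fs_img * tau_s))
    a = np.empty_like(f)
    a[:, 0] = np.maximum(f[:, 0], 0.0)
    a[:, 1:] = np.maximum(f[:, 1:] - phi * f[:, :-1], 0.0)
    return a.reshape(np.shape(dff))


def firing_raster(activity: np.ndarray, sce_sd: float = 3.0,
                  fs_img: float = 30.0) -> FiringRaster:
    """Per-cell firing intervals: activity above mean + ``sce_sd`` SD."""
    a = np.atleast_2d(np.asarray(activity, dtype=float))
    mu = a.mean(axis=1, keepdims=True)
    sd = a.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance cell(s); "
                      "their raster rows are all-false")
    thr = mu + sce_sd * sd
    raster = a > thr
    raster[flat] = False
    return FiringRaster(raster=raster, thresholds=thr[:, 0], fs_img=fs_img)


def transient_intervals(raster_row: np.ndarray, fs_img: float,
                        t0: float = 0.0) -> np.ndarray:
    """(n, 2) start/end times (s) of a cell's firing intervals, half-open."""
    r = np.asarray(raster_row, dtype=bool)
    d = np.diff(r.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if r[0]:
        starts = np.r_[0, starts]
    if r[-1]:
        ends = np.r_[ends, len(r)]
    return np.column_stack([t0 + starts / fs_img, t0 + ends / fs_img])


def coactivity_counts(raster: np.ndarray, sce_frames: int = 5) -> np.ndarray:
    """Number of cells firing within the centered ``sce_frames`` window.

    A cell counts at frame t when it has at least one firing frame in the
    window centered on t (edges truncated).
    """
    r = np.asarray(raster, dtype=bool)
    active = maximum_filter1d(r.astype(np.uint8), size=sce_frames, axis=1,
                              mode="constant", cval=0)
    return active.sum(axis=0).astype(int)


def sce_threshold(raster: np.ndarray, sce_frames: int = 5,
                  n_shuffles: int = 20, pct: float = 95.0,
                  seed: int | np.random.Generator = 0) -> float:
    """SCE count threshold from circular shuffles of the firing intervals.

    Each shuffle circularly shifts every cell's raster row by an independent
    uniform offset; the ``pct`` percentile of the pooled per-frame counts over
    all shuffles and frames is the threshold.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    r = np.asarray(raster, dtype=bool)
    n_cells, n_frames = r.shape
    pooled = np.empty(n_shuffles * n_frames)
    row_idx = np.arange(n_frames)
    for s in range(n_shuffles):
        shifts = rng.integers(0, n_frames, size=n_cells)
        cols = (row_idx[None, :] - shifts[:, None]) % n_frames
        shuffled = r[np.arange(n_cells)[:, None], cols]
        pooled[s * n_frames:(s + 1) * n_frames] = coactivity_counts(
            shuffled, sce_frames)
    return float(np.percentile(pooled, pct))


def detect_sce(counts: np.ndarray, threshold: float, raster: np.ndarray,
               fs_img: float, sce_frames: int = 5,
               t0: float = 0.0) -> list[SCEEvent]:
    """Collapse runs of suprathreshold frames to one SCE at the peak count.

    Participants are the cells active within the ``sce_frames`` window around
    the peak frame.
    """
    counts = np.asarray(counts)
    above = counts > threshold
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(counts)]
    r = np.asarray(raster, dtype=bool)
    half = sce_frames // 2
    out = []
    for i0, i1 in zip(starts, ends):
        pk = i0 + int(np.argmax(counts[i0:i1]))
        lo = max(pk - half, 0)
        hi = min(pk + half + 1, r.shape[1])
        cells = np.flatnonzero(r[:, lo:hi].any(axis=1))
        out.append(SCEEvent(frame=pk, t=t0 + pk / fs_img,
                            n_coactive=int(counts[pk]), cells=cells))
    return out


# ----------------------------------------------------------------------
# co-occurrence
# ----------------------------------------------------------------------

def _frac_within(a: np.ndarray, b_sorted: np.ndarray, w: float) -> float:
    """Fraction of times in ``a`` with at least one time of ``b`` within w."""
    if len(a) == 0 or len(b_sorted) == 0:
        return 0.0
    i = np.searchsorted(b_sorted, a)
    d = np.full(len(a), np.inf)
    left_ok = i > 0
    d[left_ok] = a[left_ok] - b_sorted[i[left_ok] - 1]
    right_ok = i < len(b_sorted)
    d[right_ok] = np.minimum(d[right_ok], b_sorted[i[right_ok]] - a[right_ok])
    return float(np.mean(d <= w))


def cooccurrence(swr_times: np.ndarray, sce_times: np.ndarray,
                 window_ms: float = 200.0) -> tuple[float, float]:
    """(% of SWRs with an SCE within the window, and vice versa)."""
    swr = np.sort(np.asarray(swr_times, dtype=float))
    sce = np.sort(np.asarray(sce_times, dtype=float))
    if len(swr) == 0 or len(sce) == 0:
        warnings.warn("empty event list; co-occurrence reported as 0%")
        return 0.0, 0.0
    w = window_ms / 1000.0
    return (100.0 * _frac_within(swr, sce, w),
            100.0 * _frac_within(sce, swr, w))


def cooccurrence_significance(swr_times: np.ndarray, sce_times: np.ndarray,
                              duration_s: float,
                              window_ms: float = 200.0,
                              n_perm: int = 1000,
                              seed: int | np.random.Generator = 0,
                              epochs: np.ndarray | None = None
                              ) -> dict:
    """Permutation test of SWR/SCE co-occurrence (both directions).

    The SWR times are redrawn uniformly ``n_perm`` times — within the supplied
    ``epochs`` (n, 2 s intervals, e.g. immobility) when given, else within the
    whole session — and the co-occurrence recomputed each time.  p-values use
    the +1 finite-permutation correction:
    ``p = (1 + #{perm >= observed}) / (n_perm + 1)``.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    swr = np.sort(np.asarray(swr_times, dtype=float))
    sce = np.sort(np.asarray(sce_times, dtype=float))
    obs_s2c, obs_c2s = cooccurrence(swr, sce, window_ms)
    w = window_ms / 1000.0

    if epochs is not None and len(epochs):
        epochs = np.asarray(epochs, dtype=float)
        lens = epochs[:, 1] - epochs[:, 0]
        total = lens.sum()
        offsets = np.concatenate([[0.0], np.cumsum(lens)[:-1]])

        def draw(size):
            u = rng.uniform(0, total, size=size)
            k = np.searchsorted(np.cumsum(lens), u, side="right")
            return epochs[k, 0] + (u - offsets[k])
    else:
        def draw(size):
            return rng.uniform(0, duration_s, size=size)

    n_swr = len(swr)
    ge_s2c = ge_c2s = 0
    for _ in range(n_perm):
        perm = np.sort(draw(n_swr))
        s2c = 100.0 * _frac_within(perm, sce, w)
        c2s = 100.0 * _frac_within(sce, perm, w)
        if s2c >= obs_s2c:
            ge_s2c += 1
        if c2s >= obs_c2s:
            ge_c2s += 1
    return {
        "swr_to_sce_pct": obs_s2c,
        "sce_to_swr_pct": obs_c2s,
        "p_swr_to_sce": (1 + ge_s2c) / (n_perm + 1),
        "p_sce_to_swr": (1 + ge_c2s) / (n_perm + 1),
        "n_perm": n_perm,
    }
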