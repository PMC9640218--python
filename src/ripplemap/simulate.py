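"""Synthetic multimodal recordings with planted, exported ground truth.

The generator emulates the statistical structure that the downstream analyses
assume, so every stage of the pipeline can be verified without real data:

* pink (1/f) background LFP noise on a 4x4 grid,
* sharp-wave-ripple transients (Gaussian-windowed 150 Hz carriers) drawn from
  four spatiotemporal archetypes — {local, global} x {stationary, traveling} —
  planted only during immobility epochs,
* a traveling theta plane wave (running epochs only) whose per-channel phase
  lag equals distance / speed along a planted axis,
* assembly-structured calcium dF/F: disjoint cell assemblies, each preferring
  one ripple archetype, emitting GCaMP-like double-exponential transients,
* multi-unit spikes that are Poisson at baseline, gain-modulated during
  ripples, and von Mises phase-locked to the ripple carrier of a home channel.

Immobility and running epochs alternate; ripples are planted only in
immobility and theta only in running, mirroring hippocampal state dependence.
All randomness flows from ``SimSpec.rng_seed``; the same spec yields
bit-identical bundles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ChannelGeometry, RecordingBundle

ARCHETYPES = (
    "local-stationary",
    "local-traveling",
    "global-stationary",
    "global-traveling",
)


@dataclass
class SimSpec:
    """Parameters of a simulated session (defaults = study conditions)."""

    duration_s: float = 600.0
    fs_lfp: float = 1250.0          # 20 kHz supported; 1250 is ample for 120-250 Hz
    fs_img: float = 30.0
    n_cells: int = 400

    # background + behavioral state
    noise_sd_uv: float = 20.0       # broadband pink-noise SD per channel
    epoch_s: float = 30.0           # alternating immobility / running blocks

    # theta (running epochs)
    theta_hz: float = 6.0
    theta_amp_uv: float = 60.0
    theta_speed_m_s: float = 0.15
    theta_direction_deg: float = 0.0   # propagation direction, deg CCW from +x

    # sharp-wave ripples (immobility epochs)
    swr_rate_hz: float = 0.2        # within immobility; ~60 events in 10 min
    min_event_gap_s: float = 0.7
    archetype_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    ripple_hz: float = 150.0
    env_sigma_ms: tuple[float, float] = (15.0, 25.0)   # per-event uniform draw
    ripple_amp_sd: float = 8.0      # peak-channel amplitude, units of noise SD
    amp_jitter: float = 0.1         # event-level multiplicative jitter (+-10%)
    local_sigma_um: float = 300.0   # Gaussian spatial footprint of "local" events
    local_floor: float = 0.3        # amplitude floor so every channel sees the event
    global_jitter: float = 0.05     # near-flat profile jitter for "global" events
    max_delay_ms: float = 8.0       # far-edge onset delay of "traveling" events
    travel_jitter_deg: float = 5.0  # per-event jitter around the session travel axis
    complex_envelope_frac: float = 0.0  # fraction of events with two-peaked envelopes

    # assemblies -> calcium
    n_assemblies: int = 4
    assembly_size_range: tuple[int, int] = (30, 140)
    p_active_preferred: float = 0.8
    p_active_other: float = 0.05
    ca_amp: float = 1.5             # dF/F transient peak
    ca_noise_sd: float = 0.05
    ca_rise_ms: float = 50.0
    ca_decay_ms: float = 400.0
    ca_baseline_rate_hz: float = 0.01   # sparse spontaneous transients per cell

    # multi-unit activity
    n_mua: int = 3
    mua_rate_hz: float = 2.0
    mua_swr_gain: float = 20.0
    mua_kappa: float = 4.0
    mua_pref_phase: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.archetype_weights, dtype=float)
        if w.shape != (4,) or not np.isclose(w.sum(), 1.0):
            raise ValueError("archetype_weights must be 4 values summing to 1")
        if not (0.0 <= self.p_active_preferred <= 1.0
                and 0.0 <= self.p_active_other <= 1.0):
            raise ValueError("activation probabilities must lie in [0, 1]")
        if self.theta_speed_m_s <= 0:
            raise ValueError("theta wave speed must be positive")
        if self.mua_kappa < 0:
            raise ValueError("von Mises kappa must be non-negative")


@dataclass
class GroundTruth:
    """Planted structure exported alongside a synthetic bundle."""

    swr: pd.DataFrame                 # one row per planted event
    delays_ms: np.ndarray             # (n_events, n_channels) planted onset shifts
    amps: np.ndarray                  # (n_events, n_channels) planted amplitudes
    assemblies: list[np.ndarray]      # cell-id arrays, disjoint
    assembly_pref: list[str]          # preferred archetype per assembly
    activations: np.ndarray | None = None   # (n_events, n_cells) bool
    sce_frames: np.ndarray | None = None    # frame index per planted event
    mua: pd.DataFrame | None = None   # cluster_id, home channel, kappa, mu

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.swr.to_csv(path / "gt_swr.csv", index=False)
        np.savetxt(path / "gt_delays_ms.csv", self.delays_ms, delimiter=",")
        np.savetxt(path / "gt_amps.csv", self.amps, delimiter=",")
        rows = [{"assembly": i, "preferred": p, "cells":
                 " ".join(map(str, cells))}
                for i, (cells, p) in enumerate(zip(self.assemblies,
                                                   self.assembly_pref))]
        pd.DataFrame(rows).to_csv(path / "gt_assemblies.csv", index=False)
        if self.activations is not None:
            np.savetxt(path / "gt_activations.csv",
                       self.activations.astype(np.int8), fmt="%d", delimiter=",")
        if self.mua is not None:
            self.mua.to_csv(path / "gt_mua.csv", index=False)


# ----------------------------------------------------------------------
# helpers
# ----------------------------------------------------------------------

def pink_noise(n_samples: int, n_channels: int, sd: float,
               rng: np.random.Generator) -> np.ndarray:
    """Independent 1/f-amplitude noise per channel, normalized to ``sd``."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    out = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    out *= sd / out.std(axis=1, keepdims=True)
    return out


def state_epochs(duration_s: float, epoch_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Alternating (immobility, running) epochs as (n, 2) second intervals.

    The session starts immobile; a trailing partial epoch is kept.
    """
    edges = np.arange(0.0, duration_s + epoch_s, epoch_s)
    edges = np.clip(edges, 0, duration_s)
    ivals = np.column_stack([edges[:-1], edges[1:]])
    ivals = ivals[ivals[:, 0] < ivals[:, 1]]
    return ivals[0::2], ivals[1::2]


def gcamp_kernel(fs: float, rise_ms: float, decay_ms: float,
                 n_points: int | None = None) -> np.ndarray:
    """Unit-peak double-exponential calcium kernel sampled at ``fs``."""
    tr, td = rise_ms / 1000.0, decay_ms / 1000.0
    if n_points is None:
        n_points = int(np.ceil(5 * td * fs)) + 1
    t = np.arange(n_points) / fs
    k = np.exp(-t / td) - np.exp(-t / tr)
    peak = k.max()
    return k / peak if peak > 0 else k


def _travel_unit(deg: float) -> np.ndarray:
    r = np.deg2rad(deg)
    return np.array([np.cos(r), np.sin(r)])


# ----------------------------------------------------------------------
# LFP
# ----------------------------------------------------------------------

def simulate_lfp(spec: SimSpec,
                 geometry: ChannelGeometry | None = None,
                 rng: np.random.Generator | None = None
                 ) -> tuple[np.ndarray, GroundTruth, np.ndarray]:
    """Generate the LFP matrix, the planted ripple table and the state mask.

    Each planted ripple inserts, on channel c, the transient

        a_c * exp(-(t - t_e - d_c)^2 / (2 sigma^2)) * cos(2 pi f_r (t - t_e - d_c) + phi_e)

    where the amplitude profile ``a_c`` is a Gaussian spatial footprint (with a
    floor) for "local" archetypes and near-flat for "global" ones, and the
    onset shift ``d_c`` is 0 for "stationary" and a linear ramp along the
    session's travel axis (up to ``max_delay_ms``) for "traveling".  The seed
    channel of local events and the travel axis are drawn once per session:
    they model a session-stable generator site and a fixed anatomical
    propagation axis.
    """
    if geometry is None:
        geometry = ChannelGeometry.grid()
    rng = np.random.default_rng(spec.rng_seed) if rng is None else rng
    fs = spec.fs_lfp
    n = int(round(spec.duration_s * fs))
    n_ch = geometry.n_channels
    pos = geometry.positions

    lfp = pink_noise(n, n_ch, spec.noise_sd_uv, rng)
    immobile, running = state_epochs(spec.duration_s, spec.epoch_s)

    # ---- theta plane wave in running epochs -------------------------------
    tdir = _travel_unit(spec.theta_direction_deg)
    proj_m = pos @ tdir / 1e6                       # meters along travel axis
    lag_s = proj_m / spec.theta_speed_m_s
    t_axis = np.arange(n) / fs
    for a, b in running:
        i0, i1 = int(round(a * fs)), int(round(b * fs))
        if i1 <= i0:
            continue
        seg_t = t_axis[i0:i1]
        taper = np.ones(i1 - i0)
        ramp = min(int(fs), (i1 - i0) // 2)
        if ramp > 0:
            w = 0.5 - 0.5 * np.cos(np.pi * np.arange(ramp) / ramp)
            taper[:ramp] = w
            taper[-ramp:] = w[::-1]
        phase = 2 * np.pi * spec.theta_hz * (seg_t[None, :] - lag_s[:, None])
        lfp[:, i0:i1] += spec.theta_amp_uv * np.cos(phase) * taper[None, :]

    # ---- ripple event times (immobility only, minimum gap) ----------------
    margin = 0.3
    times: list[float] = []
    for a, b in immobile:
        lo, hi = a + margin, b - margin
        if hi <= lo:
            continue
        t = lo
        while True:
            t += rng.exponential(1.0 / spec.swr_rate_hz)
            if t >= hi:
                break
            if not times or t - times[-1] >= spec.min_event_gap_s:
                times.append(t)
    times_arr = np.asarray(times)
    n_ev = len(times_arr)

    # ---- per-session spatial structure ------------------------------------
    local_seed = int(rng.integers(n_ch))
    travel_axis_deg = float(rng.uniform(0, 360))
    if spec.local_sigma_um > np.hypot(*(pos.max(0) - pos.min(0))):
        warnings.warn("local footprint sigma exceeds the grid diagonal; "
                      "'local' events degenerate to global")

    archetypes = rng.choice(len(ARCHETYPES), size=n_ev,
                            p=np.asarray(spec.archetype_weights))
    delays = np.zeros((n_ev, n_ch))
    amps = np.zeros((n_ev, n_ch))
    sigmas = rng.uniform(*spec.env_sigma_ms, size=n_ev) / 1000.0
    phis = rng.uniform(0, 2 * np.pi, size=n_ev)
    scales = (spec.ripple_amp_sd * spec.noise_sd_uv
              * (1 + spec.amp_jitter * rng.uniform(-1, 1, size=n_ev)))
    two_peaked = rng.random(n_ev) < spec.complex_envelope_frac
    dist_seed = geometry.distances_from(local_seed)

    rows = []
    for e in range(n_ev):
        arch = ARCHETYPES[archetypes[e]]
        spatial, temporal = arch.split("-")
        if spatial == "local":
            prof = np.maximum(
                np.exp(-dist_seed**2 / (2 * spec.local_sigma_um**2)),
                spec.local_floor)
        else:
            prof = 1.0 + spec.global_jitter * rng.uniform(-1, 1, size=n_ch)
        amps[e] = scales[e] * prof

        if temporal == "traveling":
            u = _travel_unit(travel_axis_deg
                             + rng.uniform(-spec.travel_jitter_deg,
                                           spec.travel_jitter_deg))
            proj = pos @ u
            ramp = (proj - proj.min()) / max(proj.max() - proj.min(), 1e-12)
            delays[e] = ramp * spec.max_delay_ms / 1000.0

        t_e, sig = times_arr[e], sigmas[e]
        half = 4 * sig + delays[e].max()
        i0 = max(int((t_e - half) * fs), 0)
        i1 = min(int((t_e + half) * fs) + 1, n)
        tt = t_axis[i0:i1]
        for c in range(n_ch):
            tau = tt - t_e - delays[e, c]
            env = np.exp(-tau**2 / (2 * sig**2))
            if two_peaked[e]:
                env = env + np.exp(-(tau - 3 * sig)**2 / (2 * (0.6 * sig)**2))
                env /= env.max()
            lfp[c, i0:i1] += amps[e, c] * env * np.cos(
                2 * np.pi * spec.ripple_hz * tau + phis[e])
        rows.append({
            "event_id": e, "t": t_e, "archetype": arch,
            "seed_channel": local_seed if spatial == "local" else -1,
            "sigma_ms": sig * 1000.0, "scale_uv": scales[e],
            "travel_axis_deg": travel_axis_deg if temporal == "traveling"
            else np.nan,
            "two_peaked": bool(two_peaked[e]),
            "carrier_phase": phis[e],
        })

    state_mask = np.zeros(n, dtype=bool)
    for a, b in immobile:
        state_mask[int(round(a * fs)):int(round(b * fs))] = True

    swr = pd.DataFrame(rows, columns=["event_id", "t", "archetype",
                                      "seed_channel", "sigma_ms", "scale_uv",
                                      "travel_axis_deg", "two_peaked",
                                      "carrier_phase"])
    gt = GroundTruth(swr=swr, delays_ms=delays * 1000.0, amps=amps,
                     assemblies=[], assembly_pref=[])
    return lfp, gt, state_mask


# ----------------------------------------------------------------------
# calcium
# ----------------------------------------------------------------------

def simulate_calcium(spec: SimSpec, gt: GroundTruth,
                     rng: np.random.Generator) -> np.ndarray:
    """Assembly-structured dF/F traces locked to the planted ripples.

    Cells are partitioned into disjoint assemblies; at each planted event,
    members of assemblies preferring that archetype emit a transient with
    probability ``p_active_preferred`` and every other cell with
    ``p_active_other``.  Transients are unit-peak double-exponential kernels
    scaled by ``ca_amp``; sparse spontaneous transients and Gaussian noise are
    added on top.  Fills ``gt.assemblies``/``gt.activations``/``gt.sce_frames``.
    """
    n_frames = int(round(spec.duration_s * spec.fs_img))
    n_cells = spec.n_cells
    dff = rng.normal(0.0, spec.ca_noise_sd, size=(n_cells, n_frames))
    kernel = gcamp_kernel(spec.fs_img, spec.ca_rise_ms, spec.ca_decay_ms)
    klen = len(kernel)

    # disjoint ("orthogonal") assemblies, sizes within the configured range
    if not gt.assemblies:
        order = rng.permutation(n_cells)
        cursor = 0
        assemblies, prefs = [], []
        for a in range(spec.n_assemblies):
            size = int(rng.integers(spec.assembly_size_range[0],
                                    spec.assembly_size_range[1] + 1))
            size = min(size, n_cells - cursor)
            if size <= 0:
                warnings.warn("ran out of cells while building assemblies")
                break
            assemblies.append(np.sort(order[cursor:cursor + size]))
            prefs.append(ARCHETYPES[a % len(ARCHETYPES)])
            cursor += size
        gt.assemblies, gt.assembly_pref = assemblies, prefs

    pref_of_cell = np.full(n_cells, -1)
    for i, cells in enumerate(gt.assemblies):
        pref_of_cell[cells] = i

    events = gt.swr
    n_ev = len(events)
    activations = np.zeros((n_ev, n_cells), dtype=bool)
    sce_frames = np.zeros(n_ev, dtype=int)
    for e in range(n_ev):
        arch = events["archetype"].iloc[e]
        p = np.full(n_cells, spec.p_active_other)
        for i, pref in enumerate(gt.assembly_pref):
            if pref == arch:
                p[gt.assemblies[i]] = spec.p_active_preferred
        active = rng.random(n_cells) < p
        activations[e] = active
        f0 = int(np.ceil(events["t"].iloc[e] * spec.fs_img))
        sce_frames[e] = min(f0, n_frames - 1)
        if f0 >= n_frames:
            continue
        seg = min(klen, n_frames - f0)
        dff[active, f0:f0 + seg] += spec.ca_amp * kernel[:seg]

    # sparse spontaneous transients
    n_spont = rng.poisson(spec.ca_baseline_rate_hz * spec.duration_s,
                          size=n_cells)
    for c in range(n_cells):
        for f0 in rng.integers(0, n_frames, size=n_spont[c]):
            seg = min(klen, n_frames - f0)
            dff[c, f0:f0 + seg] += spec.ca_amp * kernel[:seg]

    gt.activations = activations
    gt.sce_frames = sce_frames
    return dff


# ----------------------------------------------------------------------
# spikes
# ----------------------------------------------------------------------

def simulate_spikes(spec: SimSpec, gt: GroundTruth,
                    geometry: ChannelGeometry,
                    rng: np.random.Generator) -> pd.DataFrame:
    """MUA spike trains: Poisson baseline + phase-locked ripple bursts.

    During each planted ripple the home-channel rate is multiplied by
    ``mua_swr_gain``; the extra spikes are placed at times where the planted
    carrier phase on the home channel equals a von Mises(mu, kappa) draw, so
    the spikes are genuinely locked to the recorded oscillation rather than to
    a hidden variable.  kappa = 0 yields uniform phases, gain = 1 plants no
    extra spikes (flat PSTH).
    """
    if spec.mua_kappa < 0:
        raise ValueError("von Mises kappa must be non-negative")
    rows = []
    homes = rng.choice(geometry.n_channels, size=spec.n_mua, replace=False)
    events = gt.swr
    mua_rows = []
    for m in range(spec.n_mua):
        home = int(homes[m])
        n_base = rng.poisson(spec.mua_rate_hz * spec.duration_s)
        t_sp = list(rng.uniform(0, spec.duration_s, size=n_base))
        extra_rate = spec.mua_rate_hz * (spec.mua_swr_gain - 1.0)
        if extra_rate > 0:
            for e in range(len(events)):
                t_e = events["t"].iloc[e]
                sig = events["sigma_ms"].iloc[e] / 1000.0
                d_home = gt.delays_ms[e, home] / 1000.0
                phi_e = _event_phase(gt, e)
                # cycles with envelope above half maximum
                width = 1.2 * sig
                n_extra = rng.poisson(extra_rate * 2 * width)
                if n_extra == 0:
                    continue
                theta = rng.vonmises(spec.mua_pref_phase, spec.mua_kappa,
                                     size=n_extra)
                cyc = 1.0 / spec.ripple_hz
                n_cyc = max(int(2 * width / cyc), 1)
                ks = rng.integers(-n_cyc // 2, n_cyc // 2 + 1, size=n_extra)
                # carrier phase: 2 pi f (t - t_e - d) + phi_e == theta (mod 2 pi)
                tau = (np.mod(theta - phi_e, 2 * np.pi)) / (2 * np.pi
                                                            * spec.ripple_hz)
                t_sp.extend(t_e + d_home + tau + ks * cyc)
        t_sp = np.sort(np.asarray(t_sp))
        t_sp = t_sp[(t_sp >= 0) & (t_sp < spec.duration_s)]
        rows.append(pd.DataFrame({"cluster_id": f"mua{m}",
                                  "channel_id": home, "t": t_sp}))
        mua_rows.append({"cluster_id": f"mua{m}", "home_channel": home,
                         "kappa": spec.mua_kappa,
                         "pref_phase": spec.mua_pref_phase})
    gt.mua = pd.DataFrame(mua_rows)
    if not rows:
        return pd.DataFrame(columns=["cluster_id", "channel_id", "t"])
    return pd.concat(rows, ignore_index=True)


def _event_phase(gt: GroundTruth, e: int) -> float:
    # carrier phase offset phi_e is stored implicitly; regenerate from the table
    return float(gt.swr["carrier_phase"].iloc[e]) if "carrier_phase" in gt.swr \
        else 0.0


def simulate_plv_probe(n_events: int = 150, kappa: float = 4.0,
                       spikes_per_event: float = 15.0,
                       plv_step: float = 0.09,
                       fs: float = 1250.0, ripple_hz: float = 150.0,
                       env_sigma_ms: float = 20.0, noise_sd: float = 0.05,
                       home_channel: int = 0,
                       seed: int = 0) -> dict:
    """A focused probe for spike-ripple phase locking across the grid.

    Plants identical ripple bursts on all 16 channels, but gives channel c a
    per-event carrier phase offset drawn wrapped-normal with a dispersion that
    grows with grid-distance rank from ``home_channel`` (zero on the home
    channel).  Spikes are placed at home-channel carrier phases drawn von
    Mises(0, kappa).  The expected per-channel PLV therefore decreases by
    ``plv_step`` per distance rank: PLV_c ~ I1(kappa)/I0(kappa) x
    (1 - plv_step * rank_c).

    Returns a dict with ``lfp``, ``fs``, ``spike_times``, ``intervals`` (per
    channel, n x 2 s), ``geometry``, ``home_channel``, ``rank`` (per channel).
    """
    if kappa < 0:
        raise ValueError("von Mises kappa must be non-negative")
    rng = np.random.default_rng(seed)
    geometry = ChannelGeometry.grid()
    n_ch = geometry.n_channels
    dist = geometry.distances_from(home_channel)
    _, rank = np.unique(np.round(dist, 6), return_inverse=True)
    atten = np.clip(1.0 - plv_step * rank, 0.05, 1.0)
    sigma = np.abs(np.sqrt(np.maximum(-2.0 * np.log(atten), 0.0)))
    # E[cos d] = exp(-sigma^2 / 2) for wrapped-normal offsets d

    spacing = 0.4
    duration = (n_events + 1) * spacing
    n = int(duration * fs)
    t_axis = np.arange(n) / fs
    lfp = rng.normal(0, noise_sd, size=(n_ch, n))
    sig = env_sigma_ms / 1000.0
    centers = spacing * (np.arange(n_events) + 1)
    spikes = []
    intervals = np.empty((n_events, 2))
    for e, t_e in enumerate(centers):
        i0 = int((t_e - 4 * sig) * fs)
        i1 = int((t_e + 4 * sig) * fs)
        tau = t_axis[i0:i1] - t_e
        env = np.exp(-tau**2 / (2 * sig**2))
        offs = rng.normal(0, sigma)
        offs[home_channel] = 0.0
        for c in range(n_ch):
            lfp[c, i0:i1] += env * np.cos(2 * np.pi * ripple_hz * tau
                                          + offs[c])
        intervals[e] = (t_e - 3 * sig, t_e + 3 * sig)
        n_sp = rng.poisson(spikes_per_event)
        theta = rng.vonmises(0.0, kappa, size=n_sp)
        cyc = 1.0 / ripple_hz
        ks = rng.integers(-2, 3, size=n_sp)
        spikes.extend(t_e + theta / (2 * np.pi * ripple_hz) + ks * cyc)
    return {"lfp": lfp, "fs": fs, "spike_times": np.sort(np.asarray(spikes)),
            "intervals": [intervals.copy() for _ in range(n_ch)],
            "geometry": geometry, "home_channel": home_channel, "rank": rank}


# ----------------------------------------------------------------------
# full bundle
# ----------------------------------------------------------------------

def simulate_bundle(spec: SimSpec,
                    with_calcium: bool = True,
                    with_spikes: bool = True
                    ) -> tuple[RecordingBundle, GroundTruth]:
    """Simulate a complete session and its ground truth.

    Returns a validated :class:`RecordingBundle` (LFP always; calcium and
    spikes optional) plus the :class:`GroundTruth` describing every planted
    event, assembly and spike-phase parameter.
    """
    rng = np.random.default_rng(spec.rng_seed)
    geometry = ChannelGeometry.grid()
    lfp, gt, state_mask = simulate_lfp(spec, geometry, rng)
    dff = cell_xy = spikes = None
    if with_calcium:
        dff = simulate_calcium(spec, gt, rng)
        cell_xy = rng.uniform(geometry.positions.min(0) - 250,
                              geometry.positions.max(0) + 250,
                              size=(spec.n_cells, 2))
    if with_spikes:
        spikes = simulate_spikes(spec, gt, geometry, rng)
    bundle = RecordingBundle(lfp=lfp.astype(np.float64), fs_lfp=spec.fs_lfp,
                             geometry=geometry, dff=dff, fs_img=spec.fs_img,
                             cell_xy=cell_xy, spikes=spikes, t0=0.0,
                             state_mask=state_mask)
    return bundle, gt
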