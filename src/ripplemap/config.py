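"""Run configuration: every numeric constant of the pipeline in one place.

The defaults are the analysis constants of the study this package reimplements:
a 120-250 Hz ripple band with a 4th-order zero-phase Butterworth filter, a
4.5 SD envelope threshold with 10 ms merging and a 20 ms minimum duration,
the 0.5 cross-correlation validity rule with a 13-channel minimum, the
3.5 SD dynamic-time-warping envelope screen, the 5 ms traveling and
0.6-power / >10-channel global rules, and so on.  A :class:`RunConfig` can be
serialized to / from JSON so that every result directory carries the exact
constants that produced it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class RunConfig:
    # --- SWR detection ---
    ripple_band: tuple[float, float] = (120.0, 250.0)  # Hz
    filter_order: int = 4
    swr_thresh_sd: float = 4.5
    merge_gap_ms: float = 10.0
    min_dur_ms: float = 20.0

    # --- SWR spatiotemporal features / clustering ---
    xcorr_min: float = 0.5
    min_valid_channels: int = 13
    dtw_sd: float = 3.5
    travel_ms: float = 5.0          # delay span strictly greater -> traveling
    power_active: float = 0.6       # normalized power strictly greater -> active
    global_min_channels: int = 10   # active-channel count strictly greater -> global
    delay_pad_ms: float = 50.0      # window margin around events for delay xcorr
    max_lag_ms: float = 20.0        # search range for envelope delays
    kmeans_restarts: int = 10
    k_range: tuple[int, int] = (2, 10)

    # --- synchronous calcium events ---
    sce_sd: float = 3.0
    sce_frames: int = 5
    sce_shuffles: int = 20
    sce_pct: float = 95.0
    cooccur_ms: float = 200.0
    cooccur_perms: int = 1000
    deconv_tau_s: float = 0.4       # exponential kernel decay for deconvolution

    # --- decoding ---
    feat_win_ms: float = 150.0      # [-150, +150] ms window around SWR onset
    rfe_step: int = 50
    cv_folds: int = 10
    svm_c: float = 1.0

    # --- cell assemblies ---
    part_thresh: float = 0.30
    assembly_surrogates: int = 200
    pair_pct: float = 95.0          # percentile of the per-pair null similarity
    size_pct: float = 99.0
    ratio_shuffles: int = 10000
    inorder_step: float = 0.05
    inorder_reps: int = 200

    # --- spike / phase analyses ---
    theta_band: tuple[float, float] = (4.0, 8.0)
    mua_match_radius_um: float = 100.0
    mua_match_shuffles: int = 10000
    plv_low_n: int = 20

    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.ripple_band = tuple(float(x) for x in self.ripple_band)
        self.theta_band = tuple(float(x) for x in self.theta_band)
        self.k_range = tuple(int(x) for x in self.k_range)
        if self.ripple_band[0] >= self.ripple_band[1]:
            raise ValueError("ripple_band must be (low, high) with low < high")

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ripple_band"] = list(self.ripple_band)
        d["theta_band"] = list(self.theta_band)
        d["k_range"] = list(self.k_range)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
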