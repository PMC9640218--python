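"""Domain containers and on-disk formats.

A recording session is a :class:`RecordingBundle`: a multichannel LFP matrix on
a 2D electrode grid, an optional cells x frames calcium dF/F matrix with cell
centroids, and optional sorted multi-unit spike times — all referred to one
shared clock (seconds on the LFP clock; imaging frame k occurs at
``t0 + k / fs_img``).  Intervals are half-open ``[t_start, t_end)`` and sample
indices are 0-based throughout the package.

The canonical on-disk layout is a directory with a flat little-endian binary
LFP file plus a JSON sidecar, CSV tables for calcium / centroids / spikes, and
a JSON metadata file.  ``read_bundle(write_bundle(b)) == b`` bitwise on every
payload.  An HDF5 single-file variant is provided as a convenience.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ChannelGeometry",
    "RecordingBundle",
    "read_bundle",
    "write_bundle",
    "read_bundle_h5",
    "write_bundle_h5",
    "events_to_frame",
    "write_events_csv",
    "read_events_csv",
]

_FLOAT_FMT = "%.17g"  # repr-exact for float64 -> CSV round-trips bitwise

SPIKE_COLUMNS = ["cluster_id", "channel_id", "t"]


@dataclass
class ChannelGeometry:
    """Electrode positions (micrometers) on the recording grid."""

    positions: np.ndarray          # (n_channels, 2) x, y in um
    pitch_um: float = 500.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be (n_channels, 2)")
        if len(np.unique(self.positions, axis=0)) != len(self.positions):
            raise ValueError("channel positions must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.positions)

    @classmethod
    def grid(cls, n_rows: int = 4, n_cols: int = 4, pitch_um: float = 500.0
             ) -> "ChannelGeometry":
        """The study's device: a 4x4 grid at 500 um pitch, row-major channels."""
        yy, xx = np.mgrid[0:n_rows, 0:n_cols]
        pos = np.column_stack([xx.ravel() * pitch_um, yy.ravel() * pitch_um])
        return cls(positions=pos.astype(float), pitch_um=float(pitch_um))

    def distances_from(self, channel: int) -> np.ndarray:
        d = self.positions - self.positions[channel]
        return np.hypot(d[:, 0], d[:, 1])


@dataclass
class RecordingBundle:
    """One synchronized multimodal session.

    ``dff``/``cell_xy`` and ``spikes`` are optional modalities; absent means
    ``None`` (never zero-filled).  ``spikes`` is a DataFrame with columns
    ``cluster_id, channel_id, t`` (seconds), sorted within cluster.
    """

    lfp: np.ndarray                      # (n_channels, n_samples), microvolts
    fs_lfp: float
    geometry: ChannelGeometry
    dff: np.ndarray | None = None        # (n_cells, n_frames)
    fs_img: float = 30.0
    cell_xy: np.ndarray | None = None    # (n_cells, 2) um, grid frame
    spikes: pd.DataFrame | None = None
    t0: float = 0.0                      # imaging/LFP alignment offset (s)
    state_mask: np.ndarray | None = None  # per-LFP-sample bool, True=immobility

    def __post_init__(self) -> None:
        self.lfp = np.asarray(self.lfp)
        if self.lfp.ndim != 2:
            raise ValueError("lfp must be 2D (channels x samples)")
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.lfp.shape[0] != self.geometry.n_channels:
            raise ValueError(
                f"lfp has {self.lfp.shape[0]} channels but geometry declares "
                f"{self.geometry.n_channels}")
        if self.fs_lfp <= 2 * 250.0:
            raise ValueError("fs_lfp must exceed twice the 250 Hz ripple-band edge")
        if self.dff is not None:
            self.dff = np.asarray(self.dff, dtype=float)
            if not np.isfinite(self.dff).all():
                raise ValueError("dff contains non-finite frames")
            if self.cell_xy is not None and len(self.cell_xy) != self.dff.shape[0]:
                raise ValueError("cell_xy length does not match dff cell count")
        if self.spikes is not None:
            sp = self.spikes
            missing = [c for c in SPIKE_COLUMNS if c not in sp.columns]
            if missing:
                raise ValueError(f"spike table missing columns {missing}")
            valid = set(range(self.geometry.n_channels))
            bad = set(sp["channel_id"].unique()) - valid
            if bad:
                raise ValueError(f"spike channel_id(s) {sorted(bad)} not in geometry")
            for cid, grp in sp.groupby("cluster_id"):
                t = grp["t"].to_numpy()
                if np.any(np.diff(t) < 0):
                    raise ValueError(f"non-monotone spike times in cluster {cid!r}")

    @property
    def duration_s(self) -> float:
        return self.lfp.shape[1] / self.fs_lfp

    def frame_times(self) -> np.ndarray:
        """Times (s, LFP clock) of imaging frames: t0 + k / fs_img."""
        n = 0 if self.dff is None else self.dff.shape[1]
        return self.t0 + np.arange(n) / self.fs_img

    def has_calcium(self) -> bool:
        return self.dff is not None

    def has_spikes(self) -> bool:
        return self.spikes is not None and len(self.spikes) > 0


# ----------------------------------------------------------------------
# directory bundle format: lfp.dat + sidecars
# ----------------------------------------------------------------------

def write_bundle(bundle: RecordingBundle, path: str | Path) -> list[Path]:
    """Write a bundle to ``path`` (a directory); returns the files written.

    Refuses non-finite dF/F.  The LFP is stored as flat little-endian binary
    (C order, channels x samples) with a JSON sidecar declaring dtype, rate
    and channel count; floats in CSV payloads are printed with 17 significant
    digits so the round-trip through :func:`read_bundle` is bitwise exact.
    """
    bundle.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    lfp = np.ascontiguousarray(bundle.lfp)
    le_dtype = lfp.dtype.newbyteorder("<")
    lfp.astype(le_dtype, copy=False).tofile(path / "lfp.dat")
    written.append(path / "lfp.dat")
    sidecar = {
        "fs": bundle.fs_lfp,
        "n_channels": int(lfp.shape[0]),
        "n_samples": int(lfp.shape[1]),
        "dtype": le_dtype.str,
        "order": "C",
        "layout": "channels x samples",
    }
    (path / "lfp.json").write_text(json.dumps(sidecar, indent=2))
    written.append(path / "lfp.json")

    geom = {"positions": bundle.geometry.positions.tolist(),
            "pitch_um": bundle.geometry.pitch_um}
    (path / "geometry.json").write_text(json.dumps(geom, indent=2))
    written.append(path / "geometry.json")

    meta = {"fs_img": bundle.fs_img, "t0": bundle.t0,
            "has_dff": bundle.dff is not None,
            "has_spikes": bundle.spikes is not None,
            "has_state_mask": bundle.state_mask is not None}
    (path / "meta.json").write_text(json.dumps(meta, indent=2))
    written.append(path / "meta.json")

    if bundle.dff is not None:
        np.savetxt(path / "dff.csv", bundle.dff, fmt=_FLOAT_FMT, delimiter=",")
        written.append(path / "dff.csv")
        if bundle.cell_xy is not None:
            np.savetxt(path / "cell_xy.csv", bundle.cell_xy, fmt=_FLOAT_FMT,
                       delimiter=",")
            written.append(path / "cell_xy.csv")
    if bundle.spikes is not None:
        sp = bundle.spikes[SPIKE_COLUMNS]
        sp.to_csv(path / "spikes.csv", index=False, float_format=_FLOAT_FMT)
        written.append(path / "spikes.csv")
    if bundle.state_mask is not None:
        np.savetxt(path / "state_mask.csv", bundle.state_mask.astype(np.int8),
                   fmt="%d", delimiter=",")
        written.append(path / "state_mask.csv")
    return written


def read_bundle(path: str | Path,
                geometry: ChannelGeometry | None = None) -> RecordingBundle:
    """Read a bundle directory written by :func:`write_bundle`.

    ``geometry``, if given, must agree with the stored channel count
    (mismatch is a hard error).  Missing modalities come back as ``None``.
    """
    path = Path(path)
    sidecar = json.loads((path / "lfp.json").read_text())
    dtype = np.dtype(sidecar["dtype"])
    lfp = np.fromfile(path / "lfp.dat", dtype=dtype)
    n_ch, n_s = sidecar["n_channels"], sidecar["n_samples"]
    if lfp.size != n_ch * n_s:
        raise ValueError("lfp.dat size does not match sidecar shape")
    lfp = lfp.reshape(n_ch, n_s)

    g = json.loads((path / "geometry.json").read_text())
    stored_geom = ChannelGeometry(np.asarray(g["positions"]), g["pitch_um"])
    if geometry is not None:
        if geometry.n_channels != n_ch:
            raise ValueError(
                f"sidecar declares {n_ch} channels, geometry has "
                f"{geometry.n_channels}")
        stored_geom = geometry
    elif stored_geom.n_channels != n_ch:
        raise ValueError(
            f"sidecar declares {n_ch} channels, geometry has "
            f"{stored_geom.n_channels}")

    meta = json.loads((path / "meta.json").read_text())
    dff = cell_xy = spikes = state_mask = None
    if meta.get("has_dff") and (path / "dff.csv").exists():
        dff = np.loadtxt(path / "dff.csv", delimiter=",", ndmin=2)
        if (path / "cell_xy.csv").exists():
            cell_xy = np.loadtxt(path / "cell_xy.csv", delimiter=",", ndmin=2)
    if meta.get("has_spikes") and (path / "spikes.csv").exists():
        spikes = pd.read_csv(path / "spikes.csv",
                             float_precision="round_trip")
    if meta.get("has_state_mask") and (path / "state_mask.csv").exists():
        state_mask = np.loadtxt(path / "state_mask.csv", delimiter=",",
                                dtype=np.int8).astype(bool)
    return RecordingBundle(lfp=lfp, fs_lfp=sidecar["fs"], geometry=stored_geom,
                           dff=dff, fs_img=meta["fs_img"], cell_xy=cell_xy,
                           spikes=spikes, t0=meta["t0"], state_mask=state_mask)


# ----------------------------------------------------------------------
# HDF5 convenience variant
# ----------------------------------------------------------------------

def write_bundle_h5(bundle: RecordingBundle, path: str | Path) -> None:
    bundle.validate()
    with h5py.File(path, "w") as f:
        f.create_dataset("lfp", data=bundle.lfp)
        f.attrs["fs_lfp"] = bundle.fs_lfp
        f.attrs["fs_img"] = bundle.fs_img
        f.attrs["t0"] = bundle.t0
        f.create_dataset("geometry/positions", data=bundle.geometry.positions)
        f.attrs["pitch_um"] = bundle.geometry.pitch_um
        if bundle.dff is not None:
            f.create_dataset("dff", data=bundle.dff)
        if bundle.cell_xy is not None:
            f.create_dataset("cell_xy", data=bundle.cell_xy)
        if bundle.spikes is not None:
            sp = bundle.spikes
            f.create_dataset("spikes/cluster_id",
                             data=sp["cluster_id"].astype(str).to_numpy(
                                 dtype=h5py.string_dtype()))
            f.create_dataset("spikes/channel_id", data=sp["channel_id"].to_numpy())
            f.create_dataset("spikes/t", data=sp["t"].to_numpy())
        if bundle.state_mask is not None:
            f.create_dataset("state_mask", data=bundle.state_mask)


def read_bundle_h5(path: str | Path) -> RecordingBundle:
    with h5py.File(path, "r") as f:
        geom = ChannelGeometry(f["geometry/positions"][...],
                               float(f.attrs["pitch_um"]))
        spikes = None
        if "spikes" in f:
            spikes = pd.DataFrame({
                "cluster_id": [s.decode() if isinstance(s, bytes) else s
                               for s in f["spikes/cluster_id"][...]],
                "channel_id": f["spikes/channel_id"][...],
                "t": f["spikes/t"][...]})
        return RecordingBundle(
            lfp=f["lfp"][...], fs_lfp=float(f.attrs["fs_lfp"]), geometry=geom,
            dff=f["dff"][...] if "dff" in f else None,
            fs_img=float(f.attrs["fs_img"]),
            cell_xy=f["cell_xy"][...] if "cell_xy" in f else None,
            spikes=spikes, t0=float(f.attrs["t0"]),
            state_mask=f["state_mask"][...].astype(bool)
            if "state_mask" in f else None)


# ----------------------------------------------------------------------
# event tables
# ----------------------------------------------------------------------

EVENT_COLUMNS = ["event_id", "channel_id", "t_start", "t_end", "t_peak", "label"]


def events_to_frame(rows: list[dict]) -> pd.DataFrame:
    """Build a validated event table (one row per event interval).

    ``channel_id`` may be an integer or the string ``"array"`` for grid-level
    events.  Enforces ``t_start < t_end`` and unique event ids.
    """
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    if len(df):
        if (df["t_start"] >= df["t_end"]).any():
            raise ValueError("event table has t_start >= t_end")
        if df["event_id"].duplicated().any():
            raise ValueError("event ids are not unique")
    return df


def write_events_csv(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in ("t_start", "t_end", "t_peak"):
        out[col] = out[col].map(lambda v: _FLOAT_FMT % v)
    out.to_csv(path, index=False)


def read_events_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip",
                     dtype={"label": str, "channel_id": str})
    for col in ("t_start", "t_end", "t_peak"):
        df[col] = df[col].astype(float)
    return df
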