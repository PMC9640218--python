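"""End-to-end pipeline: bundle in, result directory out.

Stages run in dependency order — ripple detection, spatiotemporal clustering,
synchronous-calcium-event detection and co-occurrence, assembly discovery and
selectivity, decoding, spike-phase analyses — and each stage's tables are
written as CSV (header row) or JSON together with the config snapshot and
seed.  Stages whose input modality is absent are skipped with a warning.
Reruns with the same bundle, config and seed reproduce the outputs
byte-identically (all floats are printed with fixed formatting and every
random draw flows from the seed).
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import assembly as asm
from . import decoding as dec
from . import sce as sce_mod
from . import spike_phase as sph
from . import spatiotemporal as st
from .config import RunConfig
from .io import RecordingBundle, events_to_frame, write_events_csv
from .swr import detect_swr

log = logging.getLogger("ripplemap")

_FMT = "%.10g"


def _write_df(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FMT)


def _mask_to_epochs(mask: np.ndarray, fs: float) -> np.ndarray:
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, len(mask)]
    return np.column_stack([starts, ends]) / fs


def run_pipeline(bundle: RecordingBundle, config: RunConfig | None = None,
                 out_dir: str | Path = "ripplemap_out",
                 seed: int | None = None) -> dict:
    """Run every applicable stage and write the result directory.

    Returns a dict of the in-memory stage products (event lists, cluster
    model, assembly set, decoding report, ...).  Raises with the stage name
    on any stage hard-error.
    """
    cfg = config or RunConfig()
    seed = cfg.rng_seed if seed is None else seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    snap = cfg.to_dict()
    snap["rng_seed"] = seed
    (out / "config.json").write_text(json.dumps(snap, indent=2,
                                                sort_keys=True))
    results: dict = {"config": cfg, "seed": seed}

    # ---- stage: SWR detection -----------------------------------------
    try:
        ch_events, arr_events, filt, env = detect_swr(
            bundle.lfp, bundle.fs_lfp, cfg, stat_mask=None)
    except Exception as e:
        raise RuntimeError(f"stage swr_detection failed: {e}") from e
    results["channel_events"] = ch_events
    results["array_events"] = arr_events
    rows = [{"event_id": f"c{ev.channel_id}_{i}", "channel_id": ev.channel_id,
             "t_start": ev.t_start, "t_end": ev.t_end, "t_peak": ev.t_peak,
             "label": ""}
            for evs in ch_events for i, ev in enumerate(evs)]
    write_events_csv(events_to_frame(rows), out / "swr_channel_events.csv")

    # ---- stage: spatiotemporal clustering -----------------------------
    model = None
    kept_ids: list[int] = []
    try:
        fvs, feats, delays, powers, kept_ids = st.extract_event_features(
            arr_events, filt, env, bundle.fs_lfp, bundle.geometry, cfg)
        if len(kept_ids) >= 2 * cfg.k_range[0]:
            model = st.cluster_events(feats, delays, powers, cfg.k_range,
                                      cfg.kmeans_restarts, seed, cfg)
        else:
            warnings.warn("too few retained events; clustering skipped")
    except Exception as e:
        raise RuntimeError(f"stage swr_spatiotemporal failed: {e}") from e
    results["feature_vectors"] = fvs
    results["cluster_model"] = model
    results["kept_event_ids"] = kept_ids
    ev_by_id = {ev.event_id: ev for ev in arr_events}
    lab = {eid: (model.group_labels[model.assignments[i]] if model else "")
           for i, eid in enumerate(kept_ids)}
    rows = [{"event_id": ev.event_id, "channel_id": "array",
             "t_start": ev.t_start, "t_end": ev.t_end, "t_peak": ev.t_peak,
             "label": lab.get(ev.event_id, "")}
            for ev in arr_events]
    write_events_csv(events_to_frame(rows), out / "swr_array_events.csv")
    if model is not None:
        feat_df = pd.DataFrame(
            feats, columns=[f"delay_{i}" for i in range(delays.shape[1])]
            + [f"power_{i}" for i in range(powers.shape[1])])
        feat_df.insert(0, "event_id", kept_ids)
        _write_df(feat_df, out / "features.csv")
        _write_df(pd.DataFrame({"event_id": kept_ids,
                                "cluster": model.assignments,
                                "group": model.group_of_events()}),
                  out / "assignments.csv")
        _write_df(pd.DataFrame(model.templates_scaled), out / "templates.csv")
        (out / "groups.json").write_text(json.dumps(
            {"k": model.k, "group_labels": model.group_labels,
             "inertia_by_k": {str(k): v
                              for k, v in model.inertia_by_k.items()}},
            indent=2, sort_keys=True))

    onsets = np.asarray([ev_by_id[i].t_start for i in kept_ids])
    groups = model.group_of_events() if model is not None else None

    # ---- stage: SCE + co-occurrence -----------------------------------
    sce_events = None
    if bundle.has_calcium():
        try:
            activity = sce_mod.deconvolve(bundle.dff, bundle.fs_img,
                                          cfg.deconv_tau_s)
            raster = sce_mod.firing_raster(activity, cfg.sce_sd,
                                           bundle.fs_img)
            counts = sce_mod.coactivity_counts(raster.raster, cfg.sce_frames)
            thr = sce_mod.sce_threshold(raster.raster, cfg.sce_frames,
                                        cfg.sce_shuffles, cfg.sce_pct,
                                        seed)
            sce_events = sce_mod.detect_sce(counts, thr, raster.raster,
                                            bundle.fs_img, cfg.sce_frames,
                                            bundle.t0)
            sce_times = np.asarray([s.t for s in sce_events])
            swr_times = np.asarray([ev.t_start for ev in arr_events])
            epochs = (_mask_to_epochs(bundle.state_mask, bundle.fs_lfp)
                      if bundle.state_mask is not None else None)
            co = sce_mod.cooccurrence_significance(
                swr_times, sce_times, bundle.duration_s, cfg.cooccur_ms,
                cfg.cooccur_perms, seed, epochs)
            co["sce_threshold"] = thr
            co["n_sce"] = len(sce_events)
            _write_df(pd.DataFrame(
                [{"frame": s.frame, "t": s.t, "n_coactive": s.n_coactive,
                  "cells": " ".join(map(str, s.cells))}
                 for s in sce_events]), out / "sce_events.csv")
            (out / "cooccurrence.json").write_text(
                json.dumps(co, indent=2, sort_keys=True))
            results["sce_events"] = sce_events
            results["cooccurrence"] = co
            results["raster"] = raster
        except Exception as e:
            raise RuntimeError(f"stage sce_coactivity failed: {e}") from e
    else:
        log.warning("no calcium modality; SCE stage skipped")

    # ---- stage: assemblies --------------------------------------------
    assembly_set = None
    if bundle.has_calcium() and model is not None and len(onsets):
        try:
            pmat = asm.participation_matrix(
                bundle.dff, bundle.fs_img, bundle.t0, onsets,
                cfg.feat_win_ms, cfg.part_thresh)
            j = asm.jaccard_matrix(pmat.pm)
            thr_m, stack = asm.pairwise_null_threshold(
                pmat.pm, cfg.assembly_surrogates, cfg.pair_pct, seed,
                return_surrogates=True)
            pruned = asm.prune_similarity(j, thr_m)
            assembly_set = asm.detect_assemblies(pruned, stack, thr_m,
                                                 cfg.size_pct, seed)
            # pm event ids index into `onsets`, which aligns with `groups`
            labels = (np.asarray(groups)[pmat.event_ids]
                      if groups is not None else None)
            if labels is not None and len(assembly_set.assemblies):
                fr = asm.firing_ratio(assembly_set.assemblies, pmat.pm,
                                      labels, cfg.ratio_shuffles, seed)
                assembly_set.firing_ratios = fr
                _write_df(fr, out / "firing_ratios.csv")
                per_event, comp = asm.recruited_cell_counts(pmat.pm, labels)
                _write_df(per_event, out / "recruited_counts.csv")
                if len(comp):
                    _write_df(comp, out / "recruited_comparisons.csv")
            _write_df(pd.DataFrame(
                [{"assembly": i, "size": len(cells),
                  "cells": " ".join(map(str, cells))}
                 for i, cells in enumerate(assembly_set.assemblies)]),
                out / "assemblies.csv")
            np.savetxt(out / "adjacency.csv", assembly_set.similarity,
                       delimiter=",", fmt=_FMT)
            results["participation"] = pmat
            results["assembly_set"] = assembly_set
        except Exception as e:
            raise RuntimeError(f"stage assembly_analysis failed: {e}") from e
    elif bundle.has_calcium():
        log.warning("no cluster model; assembly stage skipped")

    # ---- stage: decoding ----------------------------------------------
    if bundle.has_calcium() and model is not None and groups is not None:
        try:
            X, kept_rows = dec.build_event_features(
                bundle.dff, bundle.fs_img, bundle.t0, onsets,
                cfg.feat_win_ms)
            y = np.asarray(groups)[kept_rows]
            if len(np.unique(y)) >= 2 and np.unique(
                    y, return_counts=True)[1].min() >= cfg.cv_folds:
                Xb, yb, _ = dec.balance_classes(X, y, seed)
                report = dec.train_eval_decoder(
                    Xb, yb, cfg.rfe_step, cfg.cv_folds, seed, cfg.svm_c)
                (out / "decoding_report.json").write_text(
                    json.dumps(report.to_dict(), indent=2, sort_keys=True))
                results["decoding_report"] = report
            else:
                warnings.warn("class counts too small for decoding; skipped")
        except Exception as e:
            raise RuntimeError(f"stage decoding failed: {e}") from e

    # ---- stage: spike phase -------------------------------------------
    if bundle.has_spikes():
        try:
            swr_starts = np.asarray([ev.t_start for ev in arr_events])
            intervals = [np.asarray([[e.t_start, e.t_end] for e in evs])
                         if evs else np.empty((0, 2))
                         for evs in ch_events]
            psth_rows, plv_rows = [], []
            for cid, grp in bundle.spikes.groupby("cluster_id"):
                sp_t = np.sort(grp["t"].to_numpy())
                if len(swr_starts):
                    centers, rate, sem = sph.swr_triggered_rate(
                        sp_t, swr_starts)
                    for t, r, s in zip(centers, rate, sem):
                        psth_rows.append({"cluster_id": cid, "t": t,
                                          "rate_hz": r, "sem": s})
                for res in sph.plv_map(sp_t, filt, bundle.fs_lfp, intervals,
                                       cluster_id=str(cid),
                                       low_n=cfg.plv_low_n):
                    plv_rows.append(vars(res))
            if psth_rows:
                _write_df(pd.DataFrame(psth_rows), out / "psth.csv")
            _write_df(pd.DataFrame(plv_rows), out / "plv.csv")
            results["plv"] = plv_rows
        except Exception as e:
            raise RuntimeError(f"stage spike_phase failed: {e}") from e
    else:
        log.warning("no spike modality; spike-phase stage skipped")

    return results
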