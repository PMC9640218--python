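"""Cell-assembly discovery from ripple-locked participation patterns.

A cell is *active* at a ripple when its mean dF/F in the +-150 ms window
around the event onset exceeds 0.30.  The Jaccard similarity between cells'
active-event sets gives a weighted graph; per-pair chance similarity is the
95th percentile over 200 surrogates in which each cell's active events are
resampled (same count, uniformly over events).  Sub-chance similarities are
zeroed and modularity-maximizing community detection (Louvain) partitions the
pruned graph.  Running the identical procedure on each surrogate yields a
null distribution of community sizes whose 99th percentile is the minimum
assembly size.  Surviving communities are the cell assemblies; their firing
ratio per ripple cluster is tested against 10,000 label shuffles with
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ParticipationMatrix",
    "AssemblySet",
    "participation_matrix",
    "jaccard_matrix",
    "pairwise_null_threshold",
    "detect_assemblies",
    "firing_ratio",
    "recruited_cell_counts",
]


@dataclass
class ParticipationMatrix:
    pm: np.ndarray               # (cells, events) bool
    event_ids: np.ndarray        # retained event ids (truncated windows dropped)
    window_ms: float = 150.0
    threshold: float = 0.30


@dataclass
class AssemblySet:
    assemblies: list[np.ndarray]          # disjoint cell-id arrays
    similarity: np.ndarray                # pruned Jaccard matrix
    pair_thresholds: np.ndarray           # per-pair null percentile
    size_threshold: float
    surrogate_sizes: np.ndarray           # largest community per surrogate
    all_communities: list[np.ndarray] = field(default_factory=list)
    firing_ratios: pd.DataFrame | None = None


# ----------------------------------------------------------------------

def participation_matrix(dff: np.ndarray, fs_img: float, t0: float,
                         swr_onsets: np.ndarray, window_ms: float = 150.0,
                         threshold: float = 0.30,
                         event_ids: np.ndarray | None = None
                         ) -> ParticipationMatrix:
    """Label each cell active/silent at each ripple event.

    Active = mean dF/F over the imaging frames whose times fall in the
    half-open window ``[onset - w, onset + w)`` exceeds ``threshold``.  Events
    whose window is truncated by the recording edges are dropped with a
    warning.
    """
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    onsets = np.asarray(swr_onsets, dtype=float)
    if event_ids is None:
        event_ids = np.arange(len(onsets))
    ft = t0 + np.arange(dff.shape[1]) / fs_img
    w = window_ms / 1000.0
    cols, kept = [], []
    for eid, on in zip(event_ids, onsets):
        if on - w < ft[0] or on + w > ft[-1]:
            continue
        sel = (ft >= on - w) & (ft < on + w)
        if not sel.any():
            raise ValueError("no imaging frames fall in the event window; "
                             "check fs_img / clock alignment")
        cols.append(dff[:, sel].mean(axis=1) > threshold)
        kept.append(eid)
    n_drop = len(onsets) - len(kept)
    if n_drop:
        warnings.warn(f"{n_drop} event(s) with truncated windows dropped")
    pm = np.column_stack(cols) if cols else np.zeros((dff.shape[0], 0), bool)
    return ParticipationMatrix(pm=pm, event_ids=np.asarray(kept),
                               window_ms=window_ms, threshold=threshold)


def jaccard_matrix(pm: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard similarity of the cells' active-event sets.

    ``J(i, j) = |A_i & A_j| / |A_i | A_j|``; a pair of cells that are both
    never active gets 0 (no evidence of association) and the diagonal is 1.
    """
    p = np.asarray(pm, dtype=bool)
    if p.shape[1] == 0:
        raise ValueError("participation matrix has no events")
    pf = p.astype(np.float32)
    inter = pf @ pf.T
    counts = pf.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        j = np.where(union > 0, inter / union, 0.0)
    np.fill_diagonal(j, 1.0)
    return j.astype(float)


def _surrogate_pm(pm: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shuffle the identity of each cell's active events (count preserved)."""
    n_cells, n_events = pm.shape
    k = pm.sum(axis=1)
    # rank trick: the k smallest of iid uniforms per row = uniform k-subset
    r = rng.random((n_cells, n_events))
    order = np.argsort(r, axis=1)
    ranks = np.empty_like(order)
    rows = np.arange(n_cells)[:, None]
    ranks[rows, order] = np.arange(n_events)[None, :]
    return ranks < k[:, None]


def pairwise_null_threshold(pm: np.ndarray, n_surrogates: int = 200,
                            pct: float = 95.0,
                            seed: int | np.random.Generator = 0,
                            return_surrogates: bool = False
                            ) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-pair chance-similarity threshold from event-identity shuffles.

    Each surrogate replaces every cell's active-event set by a uniform random
    subset of the same size; the ``pct`` percentile of each pair's surrogate
    similarities is its threshold.  Optionally also returns the stack of
    surrogate similarity matrices (float32) for the assembly-size null.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    pm = np.asarray(pm, dtype=bool)
    n_cells = pm.shape[0]
    stack = np.empty((n_surrogates, n_cells, n_cells), dtype=np.float32)
    for s in range(n_surrogates):
        stack[s] = jaccard_matrix(_surrogate_pm(pm, rng))
    thr = np.percentile(stack, pct, axis=0)
    return thr, (stack if return_surrogates else None)


def prune_similarity(j: np.ndarray, thr: np.ndarray) -> np.ndarray:
    """Zero similarities at or below the per-pair chance threshold.

    Strictly-above is used because the null similarity is discrete (small
    integer overlaps): a pair sitting exactly at its chance percentile carries
    no evidence of association, and keeping ties would let far more than the
    nominal (100 - pct)% of chance pairs through.  The diagonal is kept.
    """
    out = np.where(j > thr, j, 0.0)
    np.fill_diagonal(out, 1.0)
    return out


def _communities(j_pruned: np.ndarray, seed: int,
                 weighted: bool = True) -> list[np.ndarray]:
    """Louvain communities of the off-diagonal graph (isolated cells are
    singleton communities)."""
    n = j_pruned.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu = np.triu_indices(n, k=1)
    w = j_pruned[iu]
    nz = w > 0
    edges = zip(iu[0][nz].tolist(), iu[1][nz].tolist(), w[nz].tolist())
    g.add_weighted_edges_from(edges)
    comms = nx.community.louvain_communities(
        g, weight="weight" if weighted else None, seed=seed)
    return [np.sort(np.fromiter(c, dtype=int)) for c in comms]


def detect_assemblies(j_pruned: np.ndarray,
                      surrogate_stack: np.ndarray,
                      pair_thresholds: np.ndarray,
                      size_pct: float = 99.0,
                      seed: int = 0,
                      weighted: bool = True) -> AssemblySet:
    """Community detection plus the surrogate-derived size filter.

    The same pruning (per-pair thresholds) and the same community-detection
    algorithm are applied to every surrogate similarity matrix.  The size
    null is the distribution of the *largest* community per surrogate; its
    ``size_pct`` percentile is the minimum size a real community must reach
    to count as an assembly.  Using the per-surrogate maximum (rather than
    pooling all surrogate community sizes) makes the filter family-wise: a
    session with no structure at all then yields a spurious assembly in only
    ~(100 - size_pct)% of sessions, regardless of how many communities the
    partition happens to contain.
    """
    comms = _communities(j_pruned, seed=seed, weighted=weighted)
    surr_max = []
    for s in range(surrogate_stack.shape[0]):
        sp = prune_similarity(surrogate_stack[s].astype(float),
                              pair_thresholds)
        sizes = [len(c) for c in _communities(sp, seed=seed + 1 + s,
                                              weighted=weighted)]
        surr_max.append(max(sizes) if sizes else 0)
    surr_max = np.asarray(surr_max)
    size_thr = float(np.percentile(surr_max, size_pct, method="higher")) \
        if len(surr_max) else 0.0
    assemblies = [c for c in comms if len(c) >= size_thr]
    return AssemblySet(assemblies=assemblies, similarity=j_pruned,
                       pair_thresholds=pair_thresholds,
                       size_threshold=size_thr, surrogate_sizes=surr_max,
                       all_communities=comms)


# ----------------------------------------------------------------------
# selectivity
# ----------------------------------------------------------------------

def firing_ratio(assemblies: list[np.ndarray], pm: np.ndarray,
                 cluster_labels: np.ndarray,
                 n_shuffles: int = 10000,
                 seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Per-assembly, per-ripple-cluster firing ratio with a shuffle test.

    The firing ratio is the mean, over the cluster's events, of the fraction
    of assembly members active.  The null permutes the event -> cluster labels
    ``n_shuffles`` times (one shared permutation set).  Reports one-sided
    upper/lower-tail and two-sided p-values (+1 corrected), the 2.5/97.5 null
    percentiles, and Benjamini-Hochberg adjusted two-sided p across all
    (assembly x cluster) tests.  Clusters with fewer than 5 events are flagged
    low-power.  With a single cluster the ratios are computed but the
    significance columns are NaN.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    pm = np.asarray(pm, dtype=bool)
    labels = np.asarray(cluster_labels)
    if len(labels) != pm.shape[1]:
        raise ValueError("cluster labels must cover the participation events")
    clusters = np.unique(labels)
    single = len(clusters) < 2
    n_events = pm.shape[1]
    if not single:
        perm_idx = np.argsort(rng.random((n_shuffles, n_events)), axis=1)
    rows = []
    for a, cells in enumerate(assemblies):
        f = pm[cells].mean(axis=0)            # per-event member fraction
        f_perm = f[perm_idx] if not single else None
        for c in clusters:
            sel = labels == c
            obs = float(f[sel].mean())
            row = {"assembly": a, "cluster": c, "n_events": int(sel.sum()),
                   "ratio": obs, "low_power": bool(sel.sum() < 5)}
            if single:
                row.update({"p_upper": np.nan, "p_lower": np.nan,
                            "p_two": np.nan, "null_lo": np.nan,
                            "null_hi": np.nan})
            else:
                null = f_perm[:, sel].mean(axis=1)
                ge = int((null >= obs).sum())
                le = int((null <= obs).sum())
                p_up = (1 + ge) / (n_shuffles + 1)
                p_lo = (1 + le) / (n_shuffles + 1)
                row.update({"p_upper": p_up, "p_lower": p_lo,
                            "p_two": min(1.0, 2 * min(p_up, p_lo)),
                            "null_lo": float(np.percentile(null, 2.5)),
                            "null_hi": float(np.percentile(null, 97.5))})
            rows.append(row)
    df = pd.DataFrame(rows)
    if not single and len(df):
        df["p_two_fdr"] = multipletests(df["p_two"], method="fdr_bh")[1]
    else:
        df["p_two_fdr"] = np.nan
    return df


def recruited_cell_counts(pm: np.ndarray, cluster_labels: np.ndarray,
                          group_of_cluster: dict | None = None
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Active-cell counts per event, compared across clusters (and groups).

    Returns the per-event table and a pairwise rank-sum comparison table
    (Benjamini-Hochberg corrected).
    """
    pm = np.asarray(pm, dtype=bool)
    if pm.size == 0:
        raise ValueError("empty participation matrix")
    labels = np.asarray(cluster_labels)
    counts = pm.sum(axis=0)
    per_event = pd.DataFrame({"cluster": labels, "n_active": counts})
    if group_of_cluster is not None:
        per_event["group"] = [group_of_cluster[c] for c in labels]
    key = "group" if group_of_cluster is not None else "cluster"
    cats = sorted(per_event[key].unique())
    rows = []
    for i in range(len(cats)):
        for j in range(i + 1, len(cats)):
            a = per_event.loc[per_event[key] == cats[i], "n_active"]
            b = per_event.loc[per_event[key] == cats[j], "n_active"]
            stat, p = stats.ranksums(a, b)
            rows.append({key + "_a": cats[i], key + "_b": cats[j],
                         "stat": stat, "p": p,
                         "median_a": float(a.median()),
                         "median_b": float(b.median())})
    comp = pd.DataFrame(rows)
    if len(comp):
        comp["p_fdr"] = multipletests(comp["p"], method="fdr_bh")[1]
    return per_event, comp
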