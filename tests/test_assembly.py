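"""Participation, Jaccard graph, community assemblies, firing ratios."""

import numpy as np
import pytest

from ripplemap.assembly import (detect_assemblies, firing_ratio,
                                jaccard_matrix, pairwise_null_threshold,
                                participation_matrix, prune_similarity,
                                recruited_cell_counts)

FS_IMG = 30.0


# ----------------------------------------------------------------------
# participation
# ----------------------------------------------------------------------

def test_constant_dff_above_threshold_is_always_active():
    dff = np.full((2, 600), 0.5)
    dff[1] = 0.2
    pm = participation_matrix(dff, FS_IMG, 0.0, np.array([5.0, 10.0, 15.0]))
    assert pm.pm[0].all()
    assert not pm.pm[1].any()


def test_truncated_windows_dropped_with_warning():
    dff = np.full((1, 300), 0.5)     # 10 s of frames
    with pytest.warns(UserWarning, match="truncated"):
        pm = participation_matrix(dff, FS_IMG, 0.0,
                                  np.array([0.05, 5.0, 9.99]))
    assert list(pm.event_ids) == [1]


# ----------------------------------------------------------------------
# jaccard
# ----------------------------------------------------------------------

def test_jaccard_identical_disjoint_and_hand_case():
    pm = np.zeros((4, 5), dtype=bool)
    pm[0, [1, 2, 3]] = True
    pm[1, [2, 3, 4]] = True     # J(0,1) = 2/4
    pm[2, [1, 2, 3]] = True     # J(0,2) = 1
    pm[3, [0]] = True           # J(0,3) = 0
    j = jaccard_matrix(pm)
    assert j[0, 1] == pytest.approx(0.5)
    assert j[0, 2] == 1.0
    assert j[0, 3] == 0.0
    assert np.allclose(j, j.T)
    assert np.all(np.diag(j) == 1.0)


def test_both_silent_pair_is_zero():
    pm = np.zeros((2, 6), dtype=bool)
    assert jaccard_matrix(pm)[0, 1] == 0.0


# ----------------------------------------------------------------------
# per-pair null
# ----------------------------------------------------------------------

def test_silent_cells_have_zero_threshold_and_zero_pruned_value():
    pm = np.zeros((3, 10), dtype=bool)
    pm[0, :5] = True
    thr, _ = pairwise_null_threshold(pm, 50, seed=0)
    assert thr[1, 2] == 0.0
    pruned = prune_similarity(jaccard_matrix(pm), thr)
    assert pruned[1, 2] == 0.0


def test_strongly_coupled_pair_survives_pruning():
    """Cells sharing most (but not all) events clear their shuffle null."""
    pm = np.zeros((2, 40), dtype=bool)
    pm[:, :20] = True               # identical half-time activity, J = 1
    thr, _ = pairwise_null_threshold(pm, 100, seed=0)
    pruned = prune_similarity(jaccard_matrix(pm), thr)
    assert thr[0, 1] < 1.0
    assert pruned[0, 1] == 1.0


def test_always_active_pair_has_degenerate_null_and_is_pruned():
    """A pair active at every event is indistinguishable from its own
    shuffle null (which is identically 1), so it carries no evidence of
    association and does not survive the strictly-above-chance rule."""
    pm = np.ones((2, 12), dtype=bool)
    thr, _ = pairwise_null_threshold(pm, 50, seed=0)
    assert thr[0, 1] == 1.0
    pruned = prune_similarity(jaccard_matrix(pm), thr)
    assert pruned[0, 1] == 0.0


def test_null_calibration_about_five_percent_of_pairs_survive():
    rng = np.random.default_rng(1)
    pm = rng.random((60, 120)) < 0.3
    thr, _ = pairwise_null_threshold(pm, 200, pct=95.0, seed=0)
    j = jaccard_matrix(pm)
    iu = np.triu_indices(60, k=1)
    frac = np.mean(j[iu] >= thr[iu])
    # independent cells: ~5% of pairs should clear their own null percentile
    assert 0.01 < frac < 0.12


# ----------------------------------------------------------------------
# assemblies
# ----------------------------------------------------------------------

def _block_pm(rng, sizes=(40, 60, 80), n_noise=0, n_events=200,
              p_in=0.9, p_out=0.05):
    """Block-structured participation: each block prefers one event subset.

    Events are split into ``max(2, len(sizes))`` groups so that no block is
    active at *every* event (a cell active everywhere is indistinguishable
    from its own shuffle null).
    """
    n_cells = sum(sizes) + n_noise
    pm = rng.random((n_cells, n_events)) < p_out
    edges = np.cumsum((0,) + sizes)
    blocks = np.array_split(np.arange(n_events), max(2, len(sizes)))
    truth = []
    for b, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        cells = np.arange(lo, hi)
        truth.append(cells)
        pm[np.ix_(cells, blocks[b])] = rng.random(
            (len(cells), len(blocks[b]))) < p_in
    return pm, truth


def _best_match_jaccard(found, truth):
    out = []
    for f in found:
        best = max(len(np.intersect1d(f, t)) / len(np.union1d(f, t))
                   for t in truth)
        out.append(best)
    return np.mean(out) if out else 0.0


def test_block_structure_recovered_as_three_assemblies():
    """Block-diagonal co-participation: communities = the planted blocks."""
    rng = np.random.default_rng(2)
    pm, truth = _block_pm(rng)
    j = jaccard_matrix(pm)
    thr, stack = pairwise_null_threshold(pm, 60, seed=0,
                                         return_surrogates=True)
    aset = detect_assemblies(prune_similarity(j, thr), stack, thr, seed=0)
    assert len(aset.assemblies) == 3
    assert _best_match_jaccard(aset.assemblies, truth) >= 0.9


def test_single_dense_block_with_noise_cells_gives_one_assembly():
    """Hard-partition communities absorb stray cells; the count is what the
    size filter controls."""
    rng = np.random.default_rng(9)
    pm, _ = _block_pm(rng, sizes=(50,), n_noise=30, n_events=120)
    j = jaccard_matrix(pm)
    thr, stack = pairwise_null_threshold(pm, 60, seed=0,
                                         return_surrogates=True)
    aset = detect_assemblies(prune_similarity(j, thr), stack, thr, seed=0)
    assert len(aset.assemblies) == 1
    # the planted members are all inside the surviving assembly
    assert np.isin(np.arange(50), aset.assemblies[0]).all()


def test_shuffled_participation_yields_no_assemblies():
    rng = np.random.default_rng(3)
    pm, _ = _block_pm(rng)
    # destroy structure: shuffle each cell's active events
    shuffled = np.zeros_like(pm)
    for c in range(pm.shape[0]):
        k = pm[c].sum()
        shuffled[c, rng.choice(pm.shape[1], size=k, replace=False)] = True
    j = jaccard_matrix(shuffled)
    thr, stack = pairwise_null_threshold(shuffled, 60, seed=1,
                                         return_surrogates=True)
    aset = detect_assemblies(prune_similarity(j, thr), stack, thr, seed=1)
    assert len(aset.assemblies) == 0


def test_detection_invariant_under_cell_relabeling():
    """Well-separated structure is recovered identically (up to the label
    permutation) regardless of the cell ordering."""
    rng = np.random.default_rng(4)
    pm, _ = _block_pm(rng, sizes=(30, 40), n_events=120)
    perm = rng.permutation(pm.shape[0])
    inv = np.argsort(perm)

    def run(p, seed):
        j = jaccard_matrix(p)
        thr, stack = pairwise_null_threshold(p, 40, seed=seed,
                                             return_surrogates=True)
        return detect_assemblies(prune_similarity(j, thr), stack, thr,
                                 seed=seed)

    a1 = run(pm, 0)
    a2 = run(pm[perm], 0)
    del inv
    sets1 = {frozenset(c.tolist()) for c in a1.assemblies}
    # row i of the permuted matrix is original cell perm[i]
    sets2 = {frozenset(perm[c].tolist()) for c in a2.assemblies}
    assert sets1 == sets2


# ----------------------------------------------------------------------
# firing ratio + recruitment
# ----------------------------------------------------------------------

def test_perfectly_selective_assembly_extreme_p():
    labels = np.repeat([0, 1], 30)
    pm = np.zeros((20, 60), dtype=bool)
    pm[:10, labels == 0] = True       # assembly 0 fires only at cluster 0
    fr = firing_ratio([np.arange(10)], pm, labels, n_shuffles=2000, seed=0)
    row0 = fr[(fr.assembly == 0) & (fr.cluster == 0)].iloc[0]
    assert row0.ratio == 1.0
    assert row0.p_upper <= 1 / 2000 + 1e-9
    row1 = fr[(fr.assembly == 0) & (fr.cluster == 1)].iloc[0]
    assert row1.ratio == 0.0
    assert row1.p_lower <= 1 / 2000 + 1e-9


def test_single_cluster_ratios_defined_significance_nan():
    pm = np.random.default_rng(5).random((10, 20)) < 0.4
    fr = firing_ratio([np.arange(5)], pm, np.zeros(20, dtype=int),
                      n_shuffles=100, seed=0)
    assert len(fr) == 1
    assert np.isfinite(fr.ratio.iloc[0])
    assert np.isnan(fr.p_two.iloc[0])


def test_null_calibration_of_firing_ratio():
    """Non-selective data: about 5% of tests significant before FDR."""
    rng = np.random.default_rng(6)
    pm = rng.random((200, 160)) < 0.3
    labels = np.repeat(np.arange(4), 40)
    assemblies = [np.arange(i * 10, (i + 1) * 10) for i in range(20)]
    fr = firing_ratio(assemblies, pm, labels, n_shuffles=1000, seed=0)
    rate = (fr.p_two < 0.05).mean()     # 80 tests
    assert rate <= 0.15


def test_recruited_counts_detect_planted_difference():
    rng = np.random.default_rng(7)
    labels = np.repeat([0, 1], 50)
    pm = np.zeros((100, 100), dtype=bool)
    pm[:, labels == 0] = rng.random((100, 50)) < 0.1
    pm[:, labels == 1] = rng.random((100, 50)) < 0.3
    per_event, comp = recruited_cell_counts(pm, labels)
    assert comp.p_fdr.iloc[0] < 0.01
    assert comp.median_a.iloc[0] < comp.median_b.iloc[0]


def test_recruited_counts_rejects_empty():
    with pytest.raises(ValueError, match="empty"):
        recruited_cell_counts(np.zeros((0, 0), bool), np.array([]))
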