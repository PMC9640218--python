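"""Decoding ripple spatiotemporal class from population calcium activity.

Single-event features are each cell's mean dF/F in the [-150, +150] ms window
around the ripple onset.  Classes (ripple clusters or groups) are balanced by
subsampling to the smallest class, and a linear maximum-margin classifier
(one-vs-rest SVM, fixed C) is evaluated with stratified 10-fold
cross-validation.  Recursive feature elimination removes the 50 cells with the
smallest aggregate |weight| per round; by default RFE runs inside each
training fold (leak-free), with a flag for the simpler whole-set variant.
The chance reference is a label-permutation null: the same CV with permuted
labels, giving a distribution around 1/k rather than a point value.

Control analyses: "holding" (cells sampled uniformly across all assemblies)
vs "in-order" (whole assemblies concatenated) decoding curves over increasing
cell fractions, and an assembly-membership shuffle null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.feature_selection import RFECV
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DecodingReport",
    "build_event_features",
    "balance_classes",
    "train_eval_decoder",
    "holding_vs_inorder",
    "assembly_label_shuffle_control",
]


@dataclass
class DecodingReport:
    accuracy: float
    precision: dict
    recall: dict
    confusion: np.ndarray
    classes: np.ndarray
    selected_features: np.ndarray      # RFE selection on the full balanced set
    n_features_by_fold: list[int]
    fold_assignments: np.ndarray
    null_accuracies: np.ndarray        # label-permutation chance reference
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": {str(k): v for k, v in self.precision.items()},
            "recall": {str(k): v for k, v in self.recall.items()},
            "confusion": self.confusion.tolist(),
            "classes": [str(c) for c in self.classes],
            "selected_features": self.selected_features.tolist(),
            "n_features_by_fold": self.n_features_by_fold,
            "null_accuracy_mean": float(self.null_accuracies.mean())
            if len(self.null_accuracies) else None,
            "null_accuracies": self.null_accuracies.tolist(),
            "seed": self.seed,
        }


def _svc(c: float = 1.0) -> LinearSVC:
    # dual coordinate descent: far faster when events < cells (the usual
    # regime here); fixed random_state keeps the shuffling deterministic
    return LinearSVC(C=c, dual=True, max_iter=10000, random_state=0)


# ----------------------------------------------------------------------

def build_event_features(dff: np.ndarray, fs_img: float, t0: float,
                         swr_onsets: np.ndarray, window_ms: float = 150.0
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Events x cells matrix of mean dF/F in the +-window around each onset.

    Events whose window falls off the recording edge are dropped (logged).
    Returns ``(X, kept_indices)``.
    """
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    ft = t0 + np.arange(dff.shape[1]) / fs_img
    w = window_ms / 1000.0
    rows, kept = [], []
    for i, on in enumerate(np.asarray(swr_onsets, dtype=float)):
        if on - w < ft[0] or on + w > ft[-1]:
            continue
        sel = (ft >= on - w) & (ft < on + w)
        if not sel.any():
            raise ValueError("no imaging frames in the feature window; "
                             "check fs_img / clock alignment")
        rows.append(dff[:, sel].mean(axis=1))
        kept.append(i)
    n_drop = len(swr_onsets) - len(kept)
    if n_drop:
        warnings.warn(f"{n_drop} event(s) at the recording edge dropped")
    return np.asarray(rows), np.asarray(kept, dtype=int)


def balance_classes(features: np.ndarray, labels: np.ndarray,
                    seed: int | np.random.Generator = 0,
                    min_per_class: int | None = None
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Subsample every class (without replacement) to the smallest class size.

    Returns ``(X_balanced, y_balanced, taken_indices)``.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes to balance")
    n_min = counts.min()
    if min_per_class is not None and n_min < min_per_class:
        raise ValueError(
            f"smallest class has {n_min} events < {min_per_class}; "
            "use fewer CV folds")
    take = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        take.append(rng.choice(idx, size=n_min, replace=False))
    take = np.sort(np.concatenate(take))
    return features[take], labels[take], take


def _rfe_select(X: np.ndarray, y: np.ndarray, step: int, seed: int,
                c: float, inner_folds: int = 5) -> np.ndarray:
    """Boolean mask of features retained by cross-validated RFE."""
    if X.shape[1] <= step:
        return np.ones(X.shape[1], dtype=bool)
    cv = StratifiedKFold(inner_folds, shuffle=True, random_state=seed)
    sel = RFECV(_svc(c), step=step, cv=cv, scoring="accuracy",
                min_features_to_select=min(step, X.shape[1]))
    sel.fit(X, y)
    return sel.support_


def train_eval_decoder(X: np.ndarray, y: np.ndarray, rfe_step: int = 50,
                       cv_folds: int = 10, seed: int = 0,
                       c: float = 1.0, rfe_in_cv: bool = True,
                       n_null: int = 50) -> DecodingReport:
    """Linear one-vs-rest SVM with RFE and stratified cross-validation.

    With ``rfe_in_cv`` (default) feature elimination is re-run inside every
    training fold, so the test fold never informs the selection; the reported
    ``selected_features`` come from one final RFE pass on the full set.  The
    permutation null refits the plain classifier on ``n_null`` label
    permutations with the same fold structure.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < cv_folds:
        raise ValueError(f"smallest class ({counts.min()}) < cv_folds "
                         f"({cv_folds}); use fewer folds")
    skf = StratifiedKFold(cv_folds, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    y_pred = np.empty_like(y)
    n_feats = []
    for f, (tr, te) in enumerate(skf.split(X, y)):
        folds[te] = f
        scaler = StandardScaler().fit(X[tr])
        Xtr, Xte = scaler.transform(X[tr]), scaler.transform(X[te])
        if rfe_in_cv:
            mask = _rfe_select(Xtr, y[tr], rfe_step, seed + f, c)
        else:
            mask = np.ones(X.shape[1], dtype=bool)
        n_feats.append(int(mask.sum()))
        clf = _svc(c).fit(Xtr[:, mask], y[tr])
        y_pred[te] = clf.predict(Xte[:, mask])

    if not rfe_in_cv:
        # simpler variant: one RFE on the whole set, then re-run the CV
        scaler = StandardScaler().fit(X)
        mask = _rfe_select(scaler.transform(X), y, rfe_step, seed, c)
        n_feats = [int(mask.sum())] * cv_folds
        for f, (tr, te) in enumerate(skf.split(X, y)):
            scaler = StandardScaler().fit(X[tr])
            clf = _svc(c).fit(scaler.transform(X[tr])[:, mask], y[tr])
            y_pred[te] = clf.predict(scaler.transform(X[te])[:, mask])

    acc = float(np.mean(y_pred == y))
    prec, rec, _, _ = precision_recall_fscore_support(
        y, y_pred, labels=classes, zero_division=0)
    conf = confusion_matrix(y, y_pred, labels=classes)

    scaler = StandardScaler().fit(X)
    final_mask = _rfe_select(scaler.transform(X), y, rfe_step, seed, c) \
        if X.shape[1] > rfe_step else np.ones(X.shape[1], dtype=bool)

    rng = np.random.default_rng(seed)
    null_acc = np.empty(n_null)
    for i in range(n_null):
        yp = rng.permutation(y)
        pred = np.empty_like(yp)
        for tr, te in StratifiedKFold(
                cv_folds, shuffle=True, random_state=seed + i).split(X, yp):
            scaler = StandardScaler().fit(X[tr])
            clf = _svc(c).fit(scaler.transform(X[tr]), yp[tr])
            pred[te] = clf.predict(scaler.transform(X[te]))
        null_acc[i] = np.mean(pred == yp)

    return DecodingReport(
        accuracy=acc,
        precision={str(cl): float(p) for cl, p in zip(classes, prec)},
        recall={str(cl): float(r) for cl, r in zip(classes, rec)},
        confusion=conf, classes=classes,
        selected_features=np.flatnonzero(final_mask),
        n_features_by_fold=n_feats, fold_assignments=folds,
        null_accuracies=null_acc, seed=seed)


# ----------------------------------------------------------------------
# controls
# ----------------------------------------------------------------------

def _cv_accuracy(X: np.ndarray, y: np.ndarray, cv_folds: int, seed: int,
                 c: float = 1.0) -> float:
    skf = StratifiedKFold(cv_folds, shuffle=True, random_state=seed)
    correct = 0
    for tr, te in skf.split(X, y):
        scaler = StandardScaler().fit(X[tr])
        clf = _svc(c).fit(scaler.transform(X[tr]), y[tr])
        correct += int((clf.predict(scaler.transform(X[te])) == y[te]).sum())
    return correct / len(y)


def holding_vs_inorder(X: np.ndarray, y: np.ndarray,
                       assemblies: list[np.ndarray],
                       fractions: np.ndarray | None = None,
                       reps: int = 200, seed: int = 0,
                       cv_folds: int = 10, c: float = 1.0,
                       cell_xy: np.ndarray | None = None) -> dict:
    """Decode from cell subsets drawn across vs within assemblies.

    At each fraction f, "holding" draws ``f * n`` cells uniformly from the
    union of all assembly cells; "in-order" concatenates whole assemblies in a
    random order and takes the first ``f * n`` cells.  Both accuracies are
    computed ``reps`` times with matched seeds; per-fraction Wilcoxon
    signed-rank tests (BH corrected) compare the paired curves.  When
    ``cell_xy`` is given the mean pairwise cell distance per draw is recorded
    (spatial-dispersion check).  Fractions leaving fewer than 2 cells are
    skipped.
    """
    if fractions is None:
        fractions = np.round(np.arange(0.05, 1.0001, 0.05), 3)
    rng = np.random.default_rng(seed)
    pool = np.concatenate(assemblies)
    n_pool = len(pool)
    rows = []
    for f in fractions:
        n_take = int(round(f * n_pool))
        if n_take < 2:
            continue
        for r in range(reps):
            hold = rng.choice(pool, size=n_take, replace=False)
            order = rng.permutation(len(assemblies))
            inorder = np.concatenate([assemblies[i] for i in order])[:n_take]
            for cond, cells in (("holding", hold), ("in-order", inorder)):
                acc = _cv_accuracy(X[:, cells], y, cv_folds,
                                   seed + r, c)
                row = {"fraction": float(f), "rep": r, "condition": cond,
                       "accuracy": acc}
                if cell_xy is not None:
                    d = cell_xy[cells]
                    diff = d[:, None, :] - d[None, :, :]
                    dist = np.sqrt((diff ** 2).sum(-1))
                    row["mean_pair_dist_um"] = float(
                        dist[np.triu_indices(len(cells), 1)].mean())
                rows.append(row)
    curves = pd.DataFrame(rows)
    tests = []
    for f, grp in curves.groupby("fraction"):
        h = grp[grp.condition == "holding"].sort_values("rep")["accuracy"]
        o = grp[grp.condition == "in-order"].sort_values("rep")["accuracy"]
        if np.allclose(h.to_numpy(), o.to_numpy()):
            p = 1.0
        else:
            p = float(stats.wilcoxon(h, o).pvalue)
        tests.append({"fraction": f, "holding_mean": float(h.mean()),
                      "inorder_mean": float(o.mean()), "p": p})
    tests = pd.DataFrame(tests)
    if len(tests):
        tests["p_fdr"] = multipletests(tests["p"], method="fdr_bh")[1]
    return {"curves": curves, "tests": tests}


def assembly_label_shuffle_control(X: np.ndarray, y: np.ndarray,
                                   assemblies: list[np.ndarray],
                                   n: int = 1000, seed: int = 0,
                                   fraction: float = 0.25,
                                   cv_folds: int = 10, c: float = 1.0) -> dict:
    """Null distribution of in-order decoding under shuffled assembly labels.

    Membership labels are permuted across all cells ``n`` times; the in-order
    decoding accuracy at ``fraction`` is recomputed per permutation and the
    observed accuracy reported as a percentile of the null.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    sizes = [len(a) for a in assemblies]
    pool = np.concatenate(assemblies)
    n_take = max(int(round(fraction * len(pool))), 2)

    def inorder_acc(asms, s):
        order = rng.permutation(len(asms))
        cells = np.concatenate([asms[i] for i in order])[:n_take]
        return _cv_accuracy(X[:, cells], y, cv_folds, s, c)

    observed = inorder_acc(assemblies, seed)
    null = np.empty(n)
    all_cells = np.arange(X.shape[1])
    for i in range(n):
        perm = rng.permutation(all_cells)
        cursor, shuffled = 0, []
        for s in sizes:
            shuffled.append(perm[cursor:cursor + s])
            cursor += s
        null[i] = inorder_acc(shuffled, seed + 1 + i)
    pct = float(np.mean(observed > null) * 100)
    return {"observed": observed, "null": null, "percentile": pct,
            "fraction": fraction}
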