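"""Nested-CV recursive feature elimination with weight-based linear rankers.

The selection procedure for one training set and one ranker (LR-RFE or
SVM-RFE):

1. For each outer CV fold, the inner CV folds decide the optimal panel size
   k*: on every inner training split, features are recursively eliminated
   along a k-schedule that shrinks by 10% per step (floor, with a forced
   decrement) down to k = 1, refitting the L2-regularized linear model at
   each step and dropping the smallest-|weight| features; the refit model at
   each step is evaluated on the inner test split, and k* maximises the mean
   asthma-class F-measure across inner folds (ties break to the smaller k).
2. Features are ranked the same way on the outer training split and the
   top-k* features are kept.
3. The per-training-set gene set is the intersection of the outer folds'
   top-k* sets.  If the intersection is empty, genes present in all but one
   fold are accepted instead and the set is flagged.

Features are standardized (per-gene zero mean / unit variance, statistics
from the fitting split only) before every fit, so |weight| is comparable
across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from .containers import ExpressionMatrix, PhenotypeTable
from .evaluate import f_measure

RANKERS = ("LR-RFE", "SVM-RFE")


@dataclass(frozen=True)
class GeneRanking:
    """Genes ordered best first, with the elimination iteration per gene
    (-1 = survived to the end of the schedule)."""

    genes: tuple[str, ...]
    elimination_iteration: dict[str, int]
    ranker: str


@dataclass(frozen=True)
class SelectedGeneSet:
    """Feature-selection output for one training set and one ranker."""

    genes: tuple[str, ...]
    ranker: str
    per_fold_k: tuple[int, ...]
    split_index: int = -1
    fallback_used: bool = False


def k_schedule(n_features: int) -> list[int]:
    """Strictly decreasing panel sizes: k -> max(floor(0.9 k), k - 1), down to 1."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    ks = [n_features]
    while ks[-1] > 1:
        k = ks[-1]
        # floor(0.9 k) is always in [1, k-1] for k >= 2, so the sequence
        # strictly decreases and terminates at 1
        ks.append(max(int(np.floor(0.9 * k)), 1))
    return ks


def standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column mean and sd from the fitting split (sd 0 mapped to 1)."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mean, sd


def _fit_linear(ranker: str, X: np.ndarray, y: np.ndarray, seed: int):
    """Fit the ranker's L2 linear model; returns (coef, intercept)."""
    if len(np.unique(y)) < 2:
        raise ValueError("single-class fold: cannot fit a ranker")
    if ranker == "LR-RFE":
        est = LogisticRegression(C=1.0, l1_ratio=0, solver="liblinear", random_state=seed)
    elif ranker == "SVM-RFE":
        est = LinearSVC(C=1.0, penalty="l2", dual=True, max_iter=5000, random_state=seed)
    else:
        raise ValueError(f"unknown ranker {ranker!r}; expected one of {RANKERS}")
    est.fit(X, y)
    return est.coef_.ravel().copy(), float(est.intercept_.ravel()[0])


def _rfe_run(
    X: np.ndarray,
    y: np.ndarray,
    ranker: str,
    schedule: list[int],
    seed: int,
    gene_ids: np.ndarray,
    X_eval: np.ndarray | None = None,
    y_eval: np.ndarray | None = None,
    single_shot: bool = False,
):
    """One recursive-elimination pass.

    Returns (order, elim_iter, per_k_f) where ``order`` is the gene index
    ranking (best first), ``elim_iter`` maps position in ``gene_ids`` to the
    elimination iteration, and ``per_k_f`` is the asthma F-measure of the
    step-k refit model on the evaluation split (or None when no eval data).

    ``single_shot`` ranks once by |weight| of the full-model fit and only
    re-evaluates top-k cuts (the non-recursive reading of the procedure).
    """
    n = X.shape[1]
    assert schedule[0] == n
    per_k_f = [] if X_eval is not None else None
    elim_iter = np.full(n, -1, dtype=int)

    if single_shot:
        coef, intercept = _fit_linear(ranker, X, y, seed)
        order = np.lexsort((gene_ids, -np.abs(coef)))
        for step, k in enumerate(schedule):
            elim_iter[order[k:]] = np.maximum(elim_iter[order[k:]], 0)
            if per_k_f is not None:
                sel = order[:k]
                c, b = (coef, intercept) if k == n else _fit_linear(ranker, X[:, sel], y, seed)
                per_k_f.append(_eval_f(X_eval[:, sel], y_eval, c, b))
        return order, elim_iter, per_k_f

    active = np.arange(n)
    ranked_batches: list[np.ndarray] = []  # eliminated batches, earliest (worst) first
    last_coef = None
    for step, k in enumerate(schedule):
        coef, intercept = _fit_linear(ranker, X[:, active], y, seed)
        last_coef = coef
        if per_k_f is not None:
            per_k_f.append(_eval_f(X_eval[:, active], y_eval, coef, intercept))
        if step + 1 == len(schedule):
            break
        n_drop = len(active) - schedule[step + 1]
        # ascending |weight|, gene id breaking ties, for a deterministic drop
        order_in_active = np.lexsort((gene_ids[active], np.abs(coef)))
        dropped = order_in_active[:n_drop]
        elim_iter[active[dropped]] = step
        # within a batch, better = larger |weight|, ties by gene id
        batch = active[dropped]
        ranked_batches.append(batch[np.lexsort((gene_ids[batch], -np.abs(coef[dropped])))])
        active = active[np.sort(order_in_active[n_drop:])]

    # survivors first (by final |weight| desc, then gene id), then later batches
    surv = active[np.lexsort((gene_ids[active], -np.abs(last_coef)))]
    order = np.concatenate([surv] + ranked_batches[::-1]) if ranked_batches else surv
    return order, elim_iter, per_k_f


def _eval_f(X_eval: np.ndarray, y_eval: np.ndarray, coef: np.ndarray, intercept: float) -> float:
    pred = (X_eval @ coef + intercept > 0).astype(int)
    return f_measure(y_eval, pred, positive=1)


def rank_features(
    em: ExpressionMatrix,
    pheno: PhenotypeTable,
    ranker: str,
    schedule: list[int] | None = None,
    seed: int = 0,
    single_shot: bool = False,
) -> GeneRanking:
    """Rank all genes by recursive elimination on the given (training) data."""
    em.require_development("rank_features")
    X = em.values.to_numpy().T
    y = pheno.y(em.sample_ids)
    genes = np.array(em.gene_ids)
    if schedule is None:
        schedule = k_schedule(X.shape[1])
    mean, sd = standardize_fit(X)
    Xs = (X - mean) / sd
    order, elim, _ = _rfe_run(Xs, y, ranker, schedule, seed, genes, single_shot=single_shot)
    return GeneRanking(
        genes=tuple(genes[order]),
        elimination_iteration={genes[i]: int(elim[i]) for i in range(len(genes))},
        ranker=ranker,
    )


def inner_cv_optimal_k(
    em: ExpressionMatrix,
    pheno: PhenotypeTable,
    inner_folds,
    ranker: str,
    schedule: list[int] | None = None,
    seed: int = 0,
    single_shot: bool = False,
) -> tuple[int, np.ndarray]:
    """Pick the panel size k* by inner cross-validation.

    For each inner fold, features are ranked on the inner training split and
    the step-k model is scored on the inner test split; k* maximises the mean
    asthma F-measure over folds, ties resolving to the smallest k.  Returns
    (k*, mean F per schedule entry).
    """
    em.require_development("inner_cv_optimal_k")
    genes = np.array(em.gene_ids)
    if schedule is None:
        schedule = k_schedule(len(genes))
    fold_scores = []
    for fi, (train_ids, test_ids) in enumerate(inner_folds):
        X_tr = em.values[list(train_ids)].to_numpy().T
        X_te = em.values[list(test_ids)].to_numpy().T
        y_tr = pheno.y(train_ids)
        y_te = pheno.y(test_ids)
        mean, sd = standardize_fit(X_tr)
        _, _, per_k = _rfe_run(
            (X_tr - mean) / sd,
            y_tr,
            ranker,
            schedule,
            seed,
            genes,
            X_eval=(X_te - mean) / sd,
            y_eval=y_te,
            single_shot=single_shot,
        )
        fold_scores.append(per_k)
    mean_f = np.mean(np.array(fold_scores), axis=0)
    # schedule is decreasing, so the last argmax among ties is the smallest k
    best = np.flatnonzero(mean_f == mean_f.max())[-1]
    return schedule[best], mean_f


def select_gene_set(
    em: ExpressionMatrix,
    pheno: PhenotypeTable,
    entry,
    ranker: str,
    seed: int = 0,
    single_shot: bool = False,
) -> SelectedGeneSet:
    """Select the predictive gene set for one training set and one ranker.

    ``entry`` is a SplitEntry; the expression matrix must contain (at least)
    the entry's training samples.
    """
    em.require_development("select_gene_set")
    em_train_full = em.subset_samples(entry.train_ids)
    schedule = k_schedule(len(em.gene_ids))
    per_fold_sets: list[set[str]] = []
    per_fold_k: list[int] = []
    for oi, (o_train, _o_test) in enumerate(entry.outer_folds):
        em_outer = em.subset_samples(o_train)
        k_star, _ = inner_cv_optimal_k(
            em_outer, pheno, entry.inner_folds[oi], ranker,
            schedule=schedule, seed=seed, single_shot=single_shot,
        )
        ranking = rank_features(
            em_outer, pheno, ranker, schedule=schedule, seed=seed, single_shot=single_shot
        )
        per_fold_sets.append(set(ranking.genes[:k_star]))
        per_fold_k.append(k_star)

    intersection = set.intersection(*per_fold_sets)
    fallback = False
    if not intersection:
        # relax: keep genes present in all but one fold
        counts: dict[str, int] = {}
        for s in per_fold_sets:
            for g in s:
                counts[g] = counts.get(g, 0) + 1
        intersection = {g for g, c in counts.items() if c >= len(per_fold_sets) - 1}
        fallback = True
        if not intersection:
            raise RuntimeError(
                f"empty gene-set intersection for ranker {ranker} even after the "
                "all-but-one-fold fallback"
            )
    ordered = tuple(g for g in em_train_full.gene_ids if g in intersection)
    return SelectedGeneSet(
        genes=ordered,
        ranker=ranker,
        per_fold_k=tuple(per_fold_k),
        split_index=entry.index,
        fallback_used=fallback,
    )
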