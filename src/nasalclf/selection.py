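"""Experiment orchestration and parsimony-adjusted model selection.

The discovery experiment repeats, over ``n_repeats`` random stratified
training/holdout splits of the development set, the whole candidate-model
construction: per ranker (LR-RFE, SVM-RFE) a gene panel is selected by
nested-CV recursive feature elimination, each of four global classifiers is
trained on the panel, and its decision threshold is optimized on the
holdout split.  Each of the eight ranker-classifier combinations therefore
contributes one proposed model per split, scored by the *adapted* measure

    holdout asthma F-measure / panel size,

which rewards parsimony.  The Friedman test on the within-split ranks of
the adapted scores, followed by the Nemenyi post-hoc critical difference,
decides the best combination; the representative model of that combination
is its best-scoring split (ties broken by the panel's mean F across the
four classifiers, then panel size, then split index), and the final
classifier refits the representative panel's algorithm on the entire
development set, carrying over the representative threshold.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .classify import ALGORITHMS, FittedModel, optimize_threshold, train_model
from .containers import ExpressionMatrix, PhenotypeTable
from .evaluate import f_measure
from .features import RANKERS, SelectedGeneSet, select_gene_set
from .util import child_seed


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the discovery pipeline (desk-scale defaults)."""

    n_repeats: int = 10
    train_size: int = 120
    k_outer: int = 3
    k_inner: int = 3
    rankers: tuple[str, ...] = RANKERS
    algorithms: tuple[str, ...] = ALGORITHMS
    n_adaboost: int = 100
    n_trees: int = 500
    alpha: float = 0.05
    final_fit: str = "dev"          # or "training_split"
    ranking: str = "rfe"            # or "single_shot"
    min_count: int = 100
    min_fraction: float = 0.5
    n_perm: int = 20
    null_n_repeats: int = 3

    def combos(self) -> list[str]:
        return [f"{r} & {a}" for r in self.rankers for a in self.algorithms]


FULL_SCALE = PipelineConfig(n_repeats=100, k_outer=5, k_inner=5, n_perm=100,
                            null_n_repeats=100)


@dataclass(frozen=True)
class ComboScore:
    split_index: int
    combo: str
    f_pos: float
    panel_size: int

    @property
    def adapted(self) -> float:
        return self.f_pos / self.panel_size


@dataclass
class ExperimentResult:
    """Scores and models from one multi-split discovery experiment."""

    adapted: pd.DataFrame            # splits x combos
    raw_f: pd.DataFrame
    panel_sizes: pd.DataFrame
    models: dict                     # (split_index, combo) -> FittedModel
    gene_sets: dict                  # (split_index, ranker) -> SelectedGeneSet
    failures: list = field(default_factory=list)


def run_split(
    em_dev: ExpressionMatrix,
    pheno: PhenotypeTable,
    entry,
    config: PipelineConfig = PipelineConfig(),
    seed: int = 0,
):
    """Run feature selection + classification + threshold optimization for
    one training/holdout split.  Returns (scores, models, gene_sets)."""
    em_dev.require_development("run_split")
    em_train = em_dev.subset_samples(entry.train_ids)
    em_holdout = em_dev.subset_samples(entry.holdout_ids)
    y_holdout = pheno.y(entry.holdout_ids)

    scores: list[ComboScore] = []
    models: dict[str, FittedModel] = {}
    gene_sets: dict[str, SelectedGeneSet] = {}
    failures: list[tuple[str, str]] = []
    for ranker in config.rankers:
        try:
            gs = select_gene_set(
                em_dev, pheno, entry, ranker,
                seed=child_seed(seed, "rfe", entry.index, ranker),
                single_shot=(config.ranking == "single_shot"),
            )
        except Exception as exc:  # a failed ranker fails its 4 combos, not the split
            failures.extend((f"{ranker} & {a}", str(exc)) for a in config.algorithms)
            continue
        gene_sets[ranker] = gs
        for algorithm in config.algorithms:
            combo = f"{ranker} & {algorithm}"
            try:
                model = train_model(
                    em_train, pheno, algorithm, panel=gs.genes,
                    seed=child_seed(seed, "clf", entry.index, combo),
                    n_adaboost=config.n_adaboost, n_trees=config.n_trees,
                    provenance={"ranker": ranker, "split_index": entry.index,
                                "fallback_used": gs.fallback_used},
                )
                preds = model.predict(em_holdout)
                t = optimize_threshold(preds.probabilities, y_holdout)
                model = model.with_threshold(t)
                f = f_measure(y_holdout, (preds.probabilities >= t).astype(int))
                scores.append(ComboScore(entry.index, combo, f, len(gs.genes)))
                models[combo] = model
            except Exception as exc:
                failures.append((combo, str(exc)))
    return scores, models, gene_sets, failures


def run_experiment(
    em_dev: ExpressionMatrix,
    pheno: PhenotypeTable,
    plan,
    config: PipelineConfig = PipelineConfig(),
    seed: int = 0,
    checkpoint_dir: str | None = None,
) -> ExperimentResult:
    """Run all splits of the plan; resumable per split via ``checkpoint_dir``."""
    combos = config.combos()
    adapted = pd.DataFrame(np.nan, index=range(plan.n_repeats), columns=combos)
    raw_f = adapted.copy()
    sizes = adapted.copy()
    models: dict = {}
    gene_sets: dict = {}
    failures: list = []

    for entry in plan.entries:
        ckpt = (
            os.path.join(checkpoint_dir, f"split_{entry.index:04d}.json")
            if checkpoint_dir
            else None
        )
        if ckpt and os.path.exists(ckpt):
            with open(ckpt) as fh:
                payload = json.load(fh)
            split_scores = [ComboScore(**s) for s in payload["scores"]]
            split_models = {c: FittedModel.from_dict(d) for c, d in payload["models"].items()}
            split_sets = {
                r: SelectedGeneSet(genes=tuple(d["genes"]), ranker=r,
                                   per_fold_k=tuple(d["per_fold_k"]),
                                   split_index=entry.index,
                                   fallback_used=d["fallback_used"])
                for r, d in payload["gene_sets"].items()
            }
            split_failures = [tuple(x) for x in payload["failures"]]
        else:
            split_scores, split_models, split_sets, split_failures = run_split(
                em_dev, pheno, entry, config, seed=seed
            )
            if ckpt:
                os.makedirs(checkpoint_dir, exist_ok=True)
                payload = {
                    "scores": [asdict(s) for s in split_scores],
                    "models": {c: m.to_dict() for c, m in split_models.items()},
                    "gene_sets": {
                        r: {"genes": list(g.genes), "per_fold_k": list(g.per_fold_k),
                            "fallback_used": g.fallback_used}
                        for r, g in split_sets.items()
                    },
                    "failures": split_failures,
                }
                with open(ckpt, "w") as fh:
                    json.dump(payload, fh)

        for s in split_scores:
            adapted.loc[entry.index, s.combo] = s.adapted
            raw_f.loc[entry.index, s.combo] = s.f_pos
            sizes.loc[entry.index, s.combo] = s.panel_size
        for c, m in split_models.items():
            models[(entry.index, c)] = m
        for r, g in split_sets.items():
            gene_sets[(entry.index, r)] = g
        failures.extend((entry.index, c, msg) for c, msg in split_failures)

    return ExperimentResult(adapted, raw_f, sizes, models, gene_sets, failures)


# ---------------------------------------------------------------------------
# Friedman / Nemenyi


#: two-tailed studentized-range-based q values for the Nemenyi test at
#: infinite df, q_alpha = q_range(alpha, K, inf) / sqrt(2); K = 2..10.
#: Values as tabulated in Demsar (2006), "Statistical comparisons of
#: classifiers over multiple data sets", JMLR 7, Table 5.
NEMENYI_Q = {
    0.05: {2: 1.960, 3: 2.343, 4: 2.569, 5: 2.728, 6: 2.850,
           7: 2.949, 8: 3.031, 9: 3.102, 10: 3.164},
    0.10: {2: 1.645, 3: 2.052, 4: 2.291, 5: 2.459, 6: 2.589,
           7: 2.693, 8: 2.780, 9: 2.855, 10: 2.920},
}


@dataclass(frozen=True)
class FriedmanNemenyiResult:
    mean_ranks: pd.Series          # per combo, 1 = best
    statistic: float
    pvalue: float
    cd: float
    alpha: float
    ordering: tuple[str, ...]      # best (lowest mean rank) first
    significant_pairs: tuple[tuple[str, str], ...]


def _within_row_ranks(scores: pd.DataFrame) -> pd.DataFrame:
    """Rank each row so the highest score gets rank 1 (ties averaged)."""
    return scores.rank(axis=1, ascending=False, method="average")


def friedman_test(scores: pd.DataFrame) -> tuple[float, float, pd.Series]:
    """Friedman chi-square over within-split ranks of K methods on N splits.

    chi2_F = 12N / (K(K+1)) * sum_j R_j^2 - 3N(K+1), df = K - 1, where R_j is
    method j's mean rank.  Splits with any missing score are excluded.
    Returns (statistic, p-value, mean ranks).
    """
    complete = scores.dropna(axis=0)
    n, k = complete.shape
    if k < 2 or n < 2:
        raise ValueError("friedman_test needs >= 2 methods and >= 2 complete splits")
    ranks = _within_row_ranks(complete)
    mean_ranks = ranks.mean(axis=0)
    stat = 12.0 * n / (k * (k + 1)) * float((mean_ranks**2).sum()) - 3.0 * n * (k + 1)
    stat = max(stat, 0.0)  # guard tiny negative round-off for constant inputs
    p = float(chi2.sf(stat, k - 1)) if stat > 0 else 1.0
    return stat, p, mean_ranks


def nemenyi_cd(k: int, n: int, alpha: float = 0.05) -> float:
    """Nemenyi critical difference: q_alpha * sqrt(K(K+1) / (6N))."""
    if alpha not in NEMENYI_Q:
        raise ValueError(f"alpha must be one of {sorted(NEMENYI_Q)}")
    if k not in NEMENYI_Q[alpha]:
        raise ValueError(f"no tabulated q for K={k} (supported: 2..10)")
    if n < 2:
        raise ValueError("n must be >= 2")
    return NEMENYI_Q[alpha][k] * np.sqrt(k * (k + 1) / (6.0 * n))


def friedman_nemenyi(scores: pd.DataFrame, alpha: float = 0.05) -> FriedmanNemenyiResult:
    stat, p, mean_ranks = friedman_test(scores)
    n = len(scores.dropna(axis=0))
    k = scores.shape[1]
    cd = nemenyi_cd(k, n, alpha)
    ordering = tuple(mean_ranks.sort_values(kind="stable").index)
    pairs = []
    for i, a in enumerate(ordering):
        for b in ordering[i + 1:]:
            if abs(mean_ranks[a] - mean_ranks[b]) > cd:
                pairs.append((a, b))
    return FriedmanNemenyiResult(mean_ranks, stat, p, cd, alpha, ordering, tuple(pairs))


# ---------------------------------------------------------------------------
# Best combination, representative model, final fit


def select_best_combo(result: ExperimentResult, fnr: FriedmanNemenyiResult) -> str:
    """Lowest mean rank of the adapted score; ties break to higher mean raw
    F-measure, then smaller mean panel size."""
    mr = fnr.mean_ranks
    best_rank = mr.min()
    tied = [c for c in mr.index if mr[c] == best_rank]
    if len(tied) == 1:
        return tied[0]
    mean_f = result.raw_f[tied].mean(axis=0)
    tied = [c for c in tied if mean_f[c] == mean_f.max()]
    if len(tied) == 1:
        return tied[0]
    mean_size = result.panel_sizes[tied].mean(axis=0)
    return min(tied, key=lambda c: (mean_size[c], c))


@dataclass(frozen=True)
class RepresentativeModel:
    combo: str
    split_index: int
    model: FittedModel

    @property
    def genes(self) -> tuple[str, ...]:
        return self.model.genes

    @property
    def threshold(self) -> float:
        return self.model.threshold


def select_representative(result: ExperimentResult, combo: str) -> RepresentativeModel:
    """Pick the best of the combo's per-split models.

    Primary: highest holdout asthma F.  Ties: highest mean asthma F of the
    same gene set across all four global classifiers on the same holdout
    (i.e. across the ranker's combos at that split); then smaller panel;
    then lower split index.
    """
    ranker = combo.split(" & ")[0]
    f_col = result.raw_f[combo].dropna()
    if f_col.empty:
        raise ValueError(f"no successful models for combo {combo!r}")
    best_f = f_col.max()
    tied = list(f_col.index[f_col == best_f])
    if len(tied) > 1:
        ranker_combos = [c for c in result.raw_f.columns if c.startswith(f"{ranker} & ")]
        cross_mean = result.raw_f.loc[tied, ranker_combos].mean(axis=1)
        tied = list(cross_mean.index[cross_mean == cross_mean.max()])
    if len(tied) > 1:
        sizes = result.panel_sizes.loc[tied, combo]
        tied = list(sizes.index[sizes == sizes.min()])
    split_index = int(min(tied))
    return RepresentativeModel(combo, split_index, result.models[(split_index, combo)])


def fit_final(
    em_dev: ExpressionMatrix,
    pheno: PhenotypeTable,
    rep: RepresentativeModel,
    config: PipelineConfig = PipelineConfig(),
    seed: int = 0,
    train_ids=None,
) -> FittedModel:
    """Refit the representative combination on the entire development set
    (or, under ``final_fit='training_split'``, on the representative split's
    training samples), carrying over the holdout-optimized threshold."""
    algorithm = rep.combo.split(" & ")[1]
    em_fit = em_dev
    if config.final_fit == "training_split":
        if train_ids is None:
            raise ValueError("training_split refit needs the representative train_ids")
        em_fit = em_dev.subset_samples(train_ids)
    model = train_model(
        em_fit, pheno, algorithm, panel=rep.genes,
        seed=child_seed(seed, "final", rep.combo),
        n_adaboost=config.n_adaboost, n_trees=config.n_trees,
        provenance={"ranker": rep.combo.split(" & ")[0],
                    "split_index": rep.split_index, "final": True},
    )
    return model.with_threshold(rep.threshold)


def fixed_geneset_pipeline(
    em_dev: ExpressionMatrix,
    pheno: PhenotypeTable,
    genes,
    plan,
    config: PipelineConfig = PipelineConfig(),
    seed: int = 0,
) -> tuple[FittedModel, pd.DataFrame]:
    """The discovery pipeline with feature selection replaced by a fixed set.

    Trains the four global classifiers on the given genes over every split,
    optimizes thresholds on the holdouts, picks the best classifier by
    Friedman mean rank of holdout F (ties to higher mean F), then refits it
    on the entire development set with its representative threshold.
    Returns (final model, splits-by-algorithm F table).
    """
    genes = tuple(genes)
    if not genes:
        raise ValueError("fixed gene set is empty")
    missing = [g for g in genes if g not in set(em_dev.gene_ids)]
    if missing:
        raise ValueError(f"genes absent from the expression universe: {missing[:10]}")

    f_table = pd.DataFrame(np.nan, index=range(plan.n_repeats), columns=list(config.algorithms))
    models: dict = {}
    for entry in plan.entries:
        em_train = em_dev.subset_samples(entry.train_ids)
        em_holdout = em_dev.subset_samples(entry.holdout_ids)
        y_holdout = pheno.y(entry.holdout_ids)
        for algorithm in config.algorithms:
            model = train_model(
                em_train, pheno, algorithm, panel=genes,
                seed=child_seed(seed, "fixed", entry.index, algorithm),
                n_adaboost=config.n_adaboost, n_trees=config.n_trees,
                provenance={"split_index": entry.index, "fixed_geneset": True},
            )
            preds = model.predict(em_holdout)
            t = optimize_threshold(preds.probabilities, y_holdout)
            model = model.with_threshold(t)
            f_table.loc[entry.index, algorithm] = f_measure(
                y_holdout, (preds.probabilities >= t).astype(int)
            )
            models[(entry.index, algorithm)] = model

    if len(config.algorithms) > 1 and plan.n_repeats > 1:
        _, _, mean_ranks = friedman_test(f_table)
        best_rank = mean_ranks.min()
        tied = [a for a in mean_ranks.index if mean_ranks[a] == best_rank]
    else:
        tied = list(config.algorithms)
    mean_f = f_table[tied].mean(axis=0)
    best_algo = min([a for a in tied if mean_f[a] == mean_f.max()])
    col = f_table[best_algo]
    rep_split = int(min(col.index[col == col.max()]))
    rep = models[(rep_split, best_algo)]
    final = train_model(
        em_dev, pheno, best_algo, panel=genes,
        seed=child_seed(seed, "fixed-final", best_algo),
        n_adaboost=config.n_adaboost, n_trees=config.n_trees,
        provenance={"fixed_geneset": True, "final": True, "split_index": rep_split},
    ).with_threshold(rep.threshold)
    return final, f_table


# ---------------------------------------------------------------------------
# End-to-end discovery


@dataclass
class DiscoveryResult:
    em_dev: ExpressionMatrix
    plan: object
    experiment: ExperimentResult
    fnr: FriedmanNemenyiResult
    best_combo: str
    representative: RepresentativeModel
    final_model: FittedModel


def discover_classifier(
    dev_counts,
    pheno: PhenotypeTable,
    config: PipelineConfig = PipelineConfig(),
    seed: int = 0,
    checkpoint_dir: str | None = None,
) -> DiscoveryResult:
    """Count matrix in, final classifier out: filter, normalize, run the
    multi-split experiment, compare combinations, refit the representative."""
    from .preprocess import FilterParams, filter_low_counts, normalize
    from .synthetic import make_split_plan

    filtered = filter_low_counts(
        dev_counts, FilterParams(config.min_count, config.min_fraction)
    )
    em_dev = normalize(filtered, role="development")
    plan = make_split_plan(
        pheno,
        n_repeats=config.n_repeats,
        train_size=config.train_size,
        k_outer=config.k_outer,
        k_inner=config.k_inner,
        seed=child_seed(seed, "plan"),
    )
    experiment = run_experiment(
        em_dev, pheno, plan, config, seed=child_seed(seed, "experiment"),
        checkpoint_dir=checkpoint_dir,
    )
    fnr = friedman_nemenyi(experiment.adapted, alpha=config.alpha)
    best = select_best_combo(experiment, fnr)
    rep = select_representative(experiment, best)
    train_ids = plan.entries[rep.split_index].train_ids
    final = fit_final(em_dev, pheno, rep, config, seed=child_seed(seed, "final"),
                      train_ids=train_ids)
    return DiscoveryResult(em_dev, plan, experiment, fnr, best, rep, final)
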