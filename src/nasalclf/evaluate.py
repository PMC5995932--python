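"""Evaluation measures and cohort-level model evaluation.

The metric suite is the one appropriate for imbalanced case-control
classification: per-class precision/recall/F-measure (asthma is the
positive class; precision of the positive class is the PPV, precision of
the negative class the NPV) and the ROC AUC computed as the Mann-Whitney
pair statistic (ties count one half).  Zero-denominator metrics return 0
with a degenerate flag rather than NaN — an all-control specificity cohort
legitimately produces TP = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ExpressionMatrix, PhenotypeTable
from .util import child_seed


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(calls: np.ndarray, labels: np.ndarray) -> ConfusionCounts:
    """Exact confusion counts; ``calls``/``labels`` are 0/1 with 1 = asthma."""
    calls = np.asarray(calls, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if calls.shape != labels.shape:
        raise ValueError("calls and labels are misaligned")
    return ConfusionCounts(
        tp=int(((calls == 1) & (labels == 1)).sum()),
        fp=int(((calls == 1) & (labels == 0)).sum()),
        fn=int(((calls == 0) & (labels == 1)).sum()),
        tn=int(((calls == 0) & (labels == 0)).sum()),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def f_measure(y_true: np.ndarray, y_pred: np.ndarray, positive: int = 1) -> float:
    """Per-class F-measure (harmonic mean of precision and recall); 0 when
    precision + recall is 0."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(((y_pred == positive) & (y_true == positive)).sum())
    p = _safe_div(tp, int((y_pred == positive).sum()))
    r = _safe_div(tp, int((y_true == positive).sum()))
    return _safe_div(2 * p * r, p + r)


def roc_auc(probs: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney statistic: P(case prob > control prob) + ties/2."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes present")
    ranks = rankdata(probs)  # average ranks handle ties as 1/2
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return float(auc)


@dataclass(frozen=True)
class ClassMetrics:
    precision_pos: float
    recall_pos: float
    f_pos: float
    precision_neg: float
    recall_neg: float
    f_neg: float
    ppv: float   # == precision_pos
    npv: float   # == precision_neg
    auc: float
    degenerate_pos: bool  # some positive-class denominator was zero
    degenerate_neg: bool


def class_metrics(
    cc: ConfusionCounts, probs: np.ndarray | None = None, labels: np.ndarray | None = None
) -> ClassMetrics:
    """Per-class precision/recall/F plus PPV/NPV and (when probabilities are
    given) the rank-statistic AUC."""
    p_pos = _safe_div(cc.tp, cc.tp + cc.fp)
    r_pos = _safe_div(cc.tp, cc.tp + cc.fn)
    p_neg = _safe_div(cc.tn, cc.tn + cc.fn)
    r_neg = _safe_div(cc.tn, cc.tn + cc.fp)
    auc = float("nan")
    if probs is not None and labels is not None:
        labels = np.asarray(labels, dtype=int)
        if 0 < labels.sum() < len(labels):
            auc = roc_auc(probs, labels)
    return ClassMetrics(
        precision_pos=p_pos,
        recall_pos=r_pos,
        f_pos=_safe_div(2 * p_pos * r_pos, p_pos + r_pos),
        precision_neg=p_neg,
        recall_neg=r_neg,
        f_neg=_safe_div(2 * p_neg * r_neg, p_neg + r_neg),
        ppv=p_pos,
        npv=p_neg,
        auc=auc,
        degenerate_pos=(cc.tp + cc.fp == 0) or (cc.tp + cc.fn == 0),
        degenerate_neg=(cc.tn + cc.fn == 0) or (cc.tn + cc.fp == 0),
    )


@dataclass(frozen=True)
class PerformanceReport:
    dataset_id: str
    model_id: str
    counts: ConfusionCounts
    metrics: ClassMetrics
    missing_gene_fraction: float
    n_positive: int
    n_negative: int
    asthma_call_rate: float

    def to_dict(self) -> dict:
        d = {
            "dataset_id": self.dataset_id,
            "model_id": self.model_id,
            "missing_gene_fraction": self.missing_gene_fraction,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "asthma_call_rate": self.asthma_call_rate,
        }
        d.update({k: v for k, v in asdict(self.counts).items()})
        d.update(asdict(self.metrics))
        return d


def evaluate_model(
    model, em: ExpressionMatrix, pheno: PhenotypeTable, dataset_id: str = ""
) -> PerformanceReport:
    """Apply a fitted model to a cohort and compute the full metric suite."""
    preds = model.predict(em)
    labels = pheno.y(preds.sample_ids)
    cc = confusion_counts(preds.calls, labels)
    metrics = class_metrics(cc, preds.probabilities, labels)
    return PerformanceReport(
        dataset_id=dataset_id,
        model_id=model.model_id,
        counts=cc,
        metrics=metrics,
        missing_gene_fraction=preds.missing_gene_fraction,
        n_positive=int(labels.sum()),
        n_negative=int((1 - labels).sum()),
        asthma_call_rate=float(np.mean(preds.calls)) if len(preds.calls) else 0.0,
    )


def apply_to_external(
    model,
    probe_matrix: pd.DataFrame,
    probe_map: pd.DataFrame,
    pheno: PhenotypeTable,
    dataset_id: str = "external",
    standardize: bool = True,
) -> PerformanceReport:
    """Evaluate on a probe-level external cohort.

    Probes are averaged to gene level; with ``standardize`` (the
    cross-platform convention) each gene is then z-scored within the
    external dataset before the model — trained on standardized development
    values — is applied.  ``standardize=False`` applies the model to the
    collapsed values directly, appropriate when the external platform is on
    the development scale (and making the path reduce exactly to the
    internal evaluation in that case).
    """
    from .preprocess import collapse_probes_to_genes

    em = collapse_probes_to_genes(probe_matrix, probe_map, role="external")
    if not standardize:
        return evaluate_model(model, em, pheno, dataset_id=dataset_id)
    vals = em.values
    sd = vals.std(axis=1, ddof=0).replace(0, 1.0)
    z = vals.sub(vals.mean(axis=1), axis=0).div(sd, axis=0)
    em_z = ExpressionMatrix(z, role="external")
    return evaluate_model(
        model.with_external_scaling(), em_z, pheno, dataset_id=dataset_id
    )


@dataclass(frozen=True)
class NullDistribution:
    metric_values: tuple[float, ...]
    mean: float
    sd: float
    real_value: float
    n_failed: int

    @property
    def separation_sds(self) -> float:
        """How many null SDs the real value sits above the null mean."""
        return (self.real_value - self.mean) / self.sd if self.sd > 0 else float("inf")


def degenerate_baseline_f(prevalence: float) -> float:
    """Asthma F-measure of the all-positive caller: 2p / (1 + p)."""
    return 2 * prevalence / (1 + prevalence)


def permutation_null(
    dev_counts,
    dev_pheno: PhenotypeTable,
    test_em: ExpressionMatrix,
    test_pheno: PhenotypeTable,
    config,
    n_perm: int = 20,
    seed: int = 0,
    real_value: float = float("nan"),
) -> NullDistribution:
    """Label-permutation null for the full discovery pipeline.

    Each permutation shuffles the development labels, re-runs the entire
    pipeline (feature selection, classification, model selection, final fit)
    on the permuted data under the given config, and evaluates the resulting
    final model on the untouched test set.  Reported metric: test-set asthma
    F-measure.
    """
    import dataclasses

    from .selection import discover_classifier  # local import to avoid a cycle
    from .synthetic import permute_labels

    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    # null pipelines run the identical procedure on fewer splits (null_n_repeats)
    null_repeats = getattr(config, "null_n_repeats", None) or config.n_repeats
    config = dataclasses.replace(config, n_repeats=null_repeats)
    values = []
    n_failed = 0
    for i in range(n_perm):
        perm = permute_labels(dev_pheno, child_seed(seed, "perm", i))
        try:
            result = discover_classifier(
                dev_counts, perm, config, seed=child_seed(seed, "perm-pipeline", i)
            )
            report = evaluate_model(result.final_model, test_em, test_pheno, "null-test")
            values.append(report.metrics.f_pos)
        except Exception:  # per-permutation failures logged, excluded, counted
            n_failed += 1
    if len(values) < 2:
        raise RuntimeError("too few successful null permutations")
    arr = np.array(values)
    return NullDistribution(
        metric_values=tuple(values),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        real_value=real_value,
        n_failed=n_failed,
    )
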