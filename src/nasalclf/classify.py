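"""Global classifiers, probabilistic prediction and threshold optimization.

Four global algorithms interpret a selected gene panel: L2-regularized
logistic regression, linear SVM, AdaBoost (100 depth-1 learners) and random
forest (500 trees); an L1-regularized logistic regression serves as the
one-step sparse baseline.  Linear models are fit on per-gene standardized
values (statistics from the fitting data only); ensembles on the raw
log2-scale values.  The linear SVM's decision values are mapped to
probabilities through a logistic link fit on the training split
(Platt-style).  The binary decision threshold is optimized on holdout data:
the candidate grid is the midpoints between consecutive distinct
probabilities plus {0, 1}, the objective the asthma-class F-measure, and a
sample exactly at the threshold is called asthma (>= rule).
"""

from __future__ import annotations

import base64
import logging
import pickle
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .containers import ExpressionMatrix, PhenotypeTable
from .evaluate import f_measure
from .features import standardize_fit

log = logging.getLogger(__name__)

ALGORITHMS = ("Logistic", "SVM-Linear", "AdaBoost", "RandomForest")
LINEAR_ALGORITHMS = {"Logistic", "SVM-Linear", "L1-Logistic"}

#: hard error above this fraction of panel genes missing at prediction time
MISSING_GENE_LIMIT = 0.2

MODEL_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PredictionSet:
    sample_ids: tuple[str, ...]
    probabilities: np.ndarray
    calls: np.ndarray  # 0/1, 1 = asthma
    missing_gene_fraction: float = 0.0


@dataclass
class FittedModel:
    algorithm: str
    genes: tuple[str, ...]
    scaler_mean: np.ndarray   # per panel gene, from the fitting data
    scaler_sd: np.ndarray
    estimator: object         # fitted sklearn estimator (opaque, picklable)
    platt: tuple[float, float] | None = None  # (a, b) for SVM decision values
    threshold: float = 0.5
    provenance: dict = field(default_factory=dict)
    input_standardized: bool = False  # True when fed per-dataset z-scores

    @property
    def model_id(self) -> str:
        ranker = self.provenance.get("ranker", "")
        split = self.provenance.get("split_index", "")
        bits = [b for b in (ranker, self.algorithm) if b]
        sid = " & ".join(bits)
        return f"{sid}[split={split}]" if split != "" else sid

    def with_external_scaling(self) -> "FittedModel":
        """Variant that interprets its input as per-dataset z-scores."""
        return replace(self, input_standardized=True)

    def with_threshold(self, threshold: float) -> "FittedModel":
        if not 0 <= threshold <= 1:
            raise ValueError("threshold must be in [0, 1]")
        return replace(self, threshold=threshold)

    # -- prediction ---------------------------------------------------------

    def _design(self, em: ExpressionMatrix) -> tuple[np.ndarray, float]:
        """Panel-aligned sample-by-gene matrix on the raw (dev) scale.

        Missing genes are imputed at the training mean (standardized 0);
        above MISSING_GENE_LIMIT missing it is an error.
        """
        gene_set = set(em.gene_ids)
        missing = [g for g in self.genes if g not in gene_set]
        frac = len(missing) / len(self.genes)
        if frac > MISSING_GENE_LIMIT:
            raise ValueError(
                f"{len(missing)}/{len(self.genes)} panel genes missing "
                f"({frac:.0%} > {MISSING_GENE_LIMIT:.0%}): {missing[:10]}"
            )
        if missing:
            log.warning("imputing %d missing panel genes at the training mean", len(missing))
        n = len(em.sample_ids)
        X = np.empty((n, len(self.genes)))
        vals = em.values
        for j, g in enumerate(self.genes):
            if g in gene_set:
                col = vals.loc[g].to_numpy(dtype=float)
                if self.input_standardized:
                    # z-scores mapped onto the development-scale distribution
                    col = col * self.scaler_sd[j] + self.scaler_mean[j]
                X[:, j] = col
            else:
                X[:, j] = self.scaler_mean[j]
        return X, frac

    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        """Probabilities from a raw-scale panel-aligned design matrix."""
        if self.algorithm in LINEAR_ALGORITHMS:
            Xs = (X - self.scaler_mean) / self.scaler_sd
            if self.algorithm == "SVM-Linear":
                d = self.estimator.decision_function(Xs)
                a, b = self.platt
                return 1.0 / (1.0 + np.exp(-(a * d + b)))
            return self.estimator.predict_proba(Xs)[:, 1]
        return self.estimator.predict_proba(X)[:, 1]

    def predict(self, em: ExpressionMatrix) -> PredictionSet:
        if len(em.sample_ids) == 0:
            return PredictionSet((), np.array([]), np.array([], dtype=int), 0.0)
        X, frac = self._design(em)
        probs = self.predict_raw(X)
        calls = (probs >= self.threshold).astype(int)
        return PredictionSet(tuple(em.sample_ids), probs, calls, frac)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "algorithm": self.algorithm,
            "genes": list(self.genes),
            "scaler": {
                "mean": self.scaler_mean.tolist(),
                "sd": self.scaler_sd.tolist(),
            },
            "params_blob": base64.b64encode(pickle.dumps(self.estimator)).decode(),
            "platt": list(self.platt) if self.platt is not None else None,
            "threshold": self.threshold,
            "provenance": self.provenance,
            "input_standardized": self.input_standardized,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        version = d.get("schema_version")
        if version != MODEL_SCHEMA_VERSION:
            raise ValueError(
                f"model schema version {version!r} not supported "
                f"(expected {MODEL_SCHEMA_VERSION})"
            )
        return cls(
            algorithm=d["algorithm"],
            genes=tuple(d["genes"]),
            scaler_mean=np.array(d["scaler"]["mean"]),
            scaler_sd=np.array(d["scaler"]["sd"]),
            estimator=pickle.loads(base64.b64decode(d["params_blob"])),
            platt=tuple(d["platt"]) if d.get("platt") is not None else None,
            threshold=d["threshold"],
            provenance=d.get("provenance", {}),
            input_standardized=d.get("input_standardized", False),
        )


def _make_estimator(algorithm: str, seed: int, n_adaboost: int = 100, n_trees: int = 500):
    if algorithm == "Logistic":
        return LogisticRegression(C=1.0, l1_ratio=0, solver="liblinear", random_state=seed)
    if algorithm == "SVM-Linear":
        return LinearSVC(C=1.0, penalty="l2", dual=True, max_iter=5000, random_state=seed)
    if algorithm == "AdaBoost":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=n_adaboost,
            random_state=seed,
        )
    if algorithm == "RandomForest":
        return RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    if algorithm == "L1-Logistic":
        return LogisticRegression(C=1.0, l1_ratio=1, solver="liblinear", random_state=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _fit_platt(decision: np.ndarray, y: np.ndarray, seed: int) -> tuple[float, float]:
    """Logistic link from SVM decision values to probabilities."""
    lr = LogisticRegression(C=1e6, solver="lbfgs", random_state=seed, max_iter=1000)
    lr.fit(decision.reshape(-1, 1), y)
    return float(lr.coef_[0, 0]), float(lr.intercept_[0])


def train_model(
    em: ExpressionMatrix,
    pheno: PhenotypeTable,
    algorithm: str,
    panel: tuple[str, ...] | None = None,
    seed: int = 0,
    n_adaboost: int = 100,
    n_trees: int = 500,
    provenance: dict | None = None,
) -> FittedModel:
    """Fit one global classifier on the panel genes (threshold left at 0.5)."""
    em.require_development("train_model")
    panel = tuple(panel) if panel is not None else tuple(em.gene_ids)
    if len(panel) == 0:
        raise ValueError("gene panel is empty")
    missing = [g for g in panel if g not in set(em.gene_ids)]
    if missing:
        raise ValueError(f"panel genes missing from the training matrix: {missing[:10]}")
    y = pheno.y(em.sample_ids)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("training data must contain both classes")

    X = em.values.loc[list(panel)].to_numpy().T
    mean, sd = standardize_fit(X)
    est = _make_estimator(algorithm, seed, n_adaboost, n_trees)
    platt = None
    if algorithm in LINEAR_ALGORITHMS:
        Xs = (X - mean) / sd
        est.fit(Xs, y)
        if algorithm == "SVM-Linear":
            platt = _fit_platt(est.decision_function(Xs), y, seed)
    else:
        est.fit(X, y)
    return FittedModel(
        algorithm=algorithm,
        genes=panel,
        scaler_mean=mean,
        scaler_sd=sd,
        estimator=est,
        platt=platt,
        provenance=dict(provenance or {}),
    )


def optimize_threshold(probs: np.ndarray, labels: np.ndarray) -> float:
    """Probability cutoff maximizing the asthma-class F-measure.

    Candidates are midpoints between consecutive sorted distinct
    probabilities, plus 0 and 1; a sample at the threshold is called asthma;
    ties resolve to the largest threshold.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("threshold optimization needs both classes")
    distinct = np.unique(probs)
    candidates = np.concatenate([[0.0, 1.0], (distinct[1:] + distinct[:-1]) / 2.0])
    best_t, best_f = 0.0, -1.0
    for t in candidates:
        f = f_measure(labels, (probs >= t).astype(int), positive=1)
        if f > best_f or (f == best_f and t > best_t):
            best_f, best_t = f, t
    return float(best_t)


def train_l1_baseline(
    em: ExpressionMatrix, pheno: PhenotypeTable, seed: int = 0, C: float = 1.0
) -> FittedModel:
    """One-step sparse baseline: L1-logistic on all genes.

    The resulting panel is the set of genes with nonzero coefficients; the
    returned model is re-expressed on that panel so it can be applied to any
    cohort containing those genes.  The threshold is left for holdout
    optimization by the caller.
    """
    em.require_development("train_l1_baseline")
    y = pheno.y(em.sample_ids)
    X = em.values.to_numpy().T
    mean, sd = standardize_fit(X)
    est = LogisticRegression(C=C, l1_ratio=1, solver="liblinear", random_state=seed)
    est.fit((X - mean) / sd, y)
    nz = np.flatnonzero(est.coef_.ravel())
    if len(nz) == 0:
        raise ValueError("all-zero model: L1 penalty eliminated every gene")
    panel = tuple(np.array(em.gene_ids)[nz])
    # refit restricted to the surviving genes so the panel is self-contained
    return train_model(em, pheno, "L1-Logistic", panel=panel, seed=seed,
                       provenance={"baseline": "L1-Logistic one-step", "C": C})
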