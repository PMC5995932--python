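"""Synthetic cohort generators.

These emulate the statistical structure of a bulk nasal-RNAseq case-control
study: negative-binomial counts with gene-wise baseline means, log-normal
library-size factors, and a planted subset of informative genes whose means
differ between cases and controls by a fixed log2 fold change with
alternating direction.  External microarray-like cohorts are emulated as
continuous log-scale intensities with several probes per gene, a platform
scale/shift, and a configurable overlap with the RNA-seq gene universe.

Everything here is a pure function of (spec, seed): equal inputs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .containers import (
    NEGATIVE_LABEL,
    POSITIVE_LABEL,
    CountMatrix,
    ExpressionMatrix,
    PhenotypeTable,
)
from .util import child_seed


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic cohort.

    Defaults mirror the development cohort the pipeline targets: 53 cases /
    97 controls, a 2000-gene desk-scale universe with 40 informative genes at
    |log2FC| = 1.5, negative-binomial dispersion 0.1, baseline means
    log10-uniform on [0.5, 3.5] and library-size factors with CV 0.3.
    """

    n_cases: int = 53
    n_controls: int = 97
    n_genes: int = 2000
    n_informative: int = 40
    log2_effect: float = 1.5
    nb_dispersion: float = 0.1
    base_mean_log_range: tuple[float, float] = (0.5, 3.5)
    libsize_cv: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for f in ("n_cases", "n_controls", "n_genes"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")
        if self.n_informative < 0:
            raise ValueError("n_informative must be >= 0")
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative must be <= n_genes")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.libsize_cv < 0:
            raise ValueError("libsize_cv must be >= 0")
        lo, hi = self.base_mean_log_range
        if not lo < hi:
            raise ValueError("base_mean_log_range must be an increasing pair")


class Cohort(NamedTuple):
    counts: CountMatrix
    phenotype: PhenotypeTable
    informative_genes: list[str]


class ExternalCohort(NamedTuple):
    probes: pd.DataFrame          # probe-by-sample log-scale intensities
    probe_map: pd.DataFrame       # columns: probe_id, gene_id
    phenotype: PhenotypeTable
    informative_genes: list[str]  # informative genes of THIS cohort


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def _sample_ids(n: int, prefix: str = "S") -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def _effects(spec: SimulationSpec) -> np.ndarray:
    """Signed log2 effects per gene: first n_informative genes, signs alternating."""
    delta = np.zeros(spec.n_genes)
    signs = np.where(np.arange(spec.n_informative) % 2 == 0, 1.0, -1.0)
    delta[: spec.n_informative] = signs * spec.log2_effect
    return delta


def _libsize_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv**2)
    # mean-one log-normal
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=n)


def _gene_params(spec: SimulationSpec) -> tuple[np.ndarray, np.ndarray]:
    """Gene-level truth shared by every cohort of a spec: baseline means and
    signed log2 effects.  Drawn from a seed stream separate from the
    sample-level noise, so a test cohort of new subjects measures the same
    genes with the same biology."""
    rng = np.random.default_rng(child_seed(spec.seed, "gene-params"))
    lo, hi = spec.base_mean_log_range
    base = 10.0 ** rng.uniform(lo, hi, size=spec.n_genes)
    return base, _effects(spec)


def generate_cohort(
    spec: SimulationSpec,
    n_cases: int | None = None,
    n_controls: int | None = None,
    cohort: str = "dev",
    sample_prefix: str = "S",
) -> Cohort:
    """Draw a case-control negative-binomial count cohort.

    Counts for gene g, sample s follow NB with mean
    ``lib_s * base_g * 2**(delta_g * case_s)`` and dispersion ``alpha``
    (variance ``mu + alpha * mu**2``).  The first ``n_informative`` genes are
    informative and are returned as the truth set.

    Gene-level parameters depend only on the spec; sample-level draws depend
    additionally on the ``cohort`` tag, so ``cohort="test"`` (with its own
    case/control sizes) yields an independent cohort of subjects measured on
    the same gene universe.
    """
    n_cases = spec.n_cases if n_cases is None else n_cases
    n_controls = spec.n_controls if n_controls is None else n_controls
    rng = np.random.default_rng(child_seed(spec.seed, "samples", cohort))
    n_samples = n_cases + n_controls
    genes = _gene_ids(spec.n_genes)
    samples = _sample_ids(n_samples, prefix=sample_prefix)

    base, delta = _gene_params(spec)
    lib = _libsize_factors(rng, n_samples, spec.libsize_cv)
    case = np.array([1] * n_cases + [0] * n_controls)

    mu = lib[None, :] * base[:, None] * 2.0 ** (delta[:, None] * case[None, :])
    # NB via gamma-Poisson mixture: shape r = 1/alpha, scale mu/r
    r = 1.0 / spec.nb_dispersion
    lam = rng.gamma(shape=r, scale=mu / r)
    counts = rng.poisson(lam).astype(np.int64)

    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=samples))
    labels = [POSITIVE_LABEL] * n_cases + [NEGATIVE_LABEL] * n_controls
    pheno = PhenotypeTable(pd.DataFrame({"label": labels}, index=pd.Index(samples, name="sample_id")))
    return Cohort(cm, pheno, genes[: spec.n_informative])


def generate_test_cohort(
    spec: SimulationSpec, n_cases: int = 13, n_controls: int = 27
) -> Cohort:
    """Independent subjects (defaults 13 cases / 27 controls) measured on the
    same synthetic gene universe as the development cohort of ``spec``."""
    return generate_cohort(spec, n_cases=n_cases, n_controls=n_controls,
                           cohort="test", sample_prefix="T")


def generate_other_condition_cohort(
    spec: SimulationSpec, n_cases: int | None = None, n_controls: int | None = None
) -> Cohort:
    """An RNA-seq cohort of a different condition on the same gene universe.

    Its case/control signal lies on genes disjoint from the asthma
    informative set; since the cohort contains no asthma subjects, the
    asthma label is uniformly negative and the condition's own case/control
    status is kept as a covariate.  Returned ``informative_genes`` are the
    condition's genes.
    """
    n_cases = spec.n_cases if n_cases is None else n_cases
    n_controls = spec.n_controls if n_controls is None else n_controls
    pool = np.arange(spec.n_informative, spec.n_genes)
    if len(pool) < spec.n_informative:
        raise ValueError("not enough non-informative genes for a disjoint signal")
    rng_pos = np.random.default_rng(child_seed(spec.seed, "other-genes"))
    info_idx = np.sort(rng_pos.choice(pool, size=spec.n_informative, replace=False))

    rng = np.random.default_rng(child_seed(spec.seed, "samples", "other"))
    n_samples = n_cases + n_controls
    genes = np.array(_gene_ids(spec.n_genes))
    samples = _sample_ids(n_samples, prefix="O")
    base, _dev_delta = _gene_params(spec)
    delta = np.zeros(spec.n_genes)
    delta[info_idx] = (
        np.where(np.arange(len(info_idx)) % 2 == 0, 1.0, -1.0) * spec.log2_effect
    )
    lib = _libsize_factors(rng, n_samples, spec.libsize_cv)
    case = np.array([1] * n_cases + [0] * n_controls)
    mu = lib[None, :] * base[:, None] * 2.0 ** (delta[:, None] * case[None, :])
    r = 1.0 / spec.nb_dispersion
    counts = rng.poisson(rng.gamma(shape=r, scale=mu / r)).astype(np.int64)

    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=samples))
    pheno = PhenotypeTable(
        pd.DataFrame(
            {"label": [NEGATIVE_LABEL] * n_samples,
             "condition": ["case"] * n_cases + ["control"] * n_controls},
            index=pd.Index(samples, name="sample_id"),
        )
    )
    return Cohort(cm, pheno, genes[info_idx].tolist())


def generate_external_cohort(
    spec: SimulationSpec,
    probes_per_gene: int = 2,
    platform_scale: float = 1.0,
    platform_shift: float = 0.0,
    gene_overlap_fraction: float = 1.0,
    disjoint_signal: bool = False,
    probe_noise_sd: float = 0.25,
    sample_noise_sd: float = 0.5,
) -> ExternalCohort:
    """Draw a microarray-like external cohort on the same gene universe.

    Gene-level log2 intensities are ``platform_scale * (log2(base) +
    delta * case) + platform_shift`` plus per-sample Gaussian noise; each gene
    is measured by ``probes_per_gene`` probes with independent probe-level
    noise.  Only ``gene_overlap_fraction`` of the RNA-seq universe is present
    (the overlap is a seeded random subset that always keeps the cohort's own
    informative genes).  With ``disjoint_signal`` the informative genes are
    sampled outside the RNA-seq informative set, emulating a cohort of a
    different condition whose signal lives elsewhere.
    """
    if probes_per_gene < 1:
        raise ValueError("probes_per_gene must be >= 1")
    if not 0 < gene_overlap_fraction <= 1:
        raise ValueError("gene_overlap_fraction must be in (0, 1]")

    rng = np.random.default_rng(child_seed(spec.seed, "external", int(disjoint_signal)))
    n_samples = spec.n_cases + spec.n_controls
    genes = np.array(_gene_ids(spec.n_genes))
    samples = _sample_ids(n_samples, prefix="E")

    base, dev_delta = _gene_params(spec)
    base_log2 = np.log2(base)
    case = np.array([1] * spec.n_cases + [0] * spec.n_controls)

    if disjoint_signal:
        pool = np.arange(spec.n_informative, spec.n_genes)
        if len(pool) < spec.n_informative:
            raise ValueError("not enough non-informative genes for a disjoint signal")
        info_idx = np.sort(rng.choice(pool, size=spec.n_informative, replace=False))
        delta = np.zeros(spec.n_genes)
        delta[info_idx] = (
            np.where(np.arange(len(info_idx)) % 2 == 0, 1.0, -1.0) * spec.log2_effect
        )
    else:
        # same informative genes and effect directions as the RNA-seq cohorts
        info_idx = np.arange(spec.n_informative)
        delta = dev_delta

    signal = base_log2[:, None] + delta[:, None] * case[None, :]
    gene_vals = platform_scale * signal + platform_shift
    if sample_noise_sd > 0:
        gene_vals = gene_vals + rng.normal(0, sample_noise_sd, size=gene_vals.shape)

    n_keep = max(int(round(gene_overlap_fraction * spec.n_genes)), len(info_idx))
    rest = np.setdiff1d(np.arange(spec.n_genes), info_idx)
    fill = rng.choice(rest, size=n_keep - len(info_idx), replace=False)
    keep_idx = np.sort(np.concatenate([info_idx, fill]))  # signal genes always measured

    probe_rows = []
    probe_ids = []
    map_rows = []
    for gi in keep_idx:
        for p in range(probes_per_gene):
            pid = f"P_{genes[gi]}_{p + 1}"
            probe_ids.append(pid)
            map_rows.append((pid, genes[gi]))
            row = gene_vals[gi]
            if probe_noise_sd > 0:
                row = row + rng.normal(0, probe_noise_sd, size=n_samples)
            probe_rows.append(row)

    probes = pd.DataFrame(np.array(probe_rows), index=probe_ids, columns=samples)
    probe_map = pd.DataFrame(map_rows, columns=["probe_id", "gene_id"])
    idx = pd.Index(samples, name="sample_id")
    if disjoint_signal:
        # an "other condition" cohort contains no asthma subjects: the asthma
        # label is uniformly negative and the cohort's own case/control
        # status rides along as a covariate
        condition = ["case"] * spec.n_cases + ["control"] * spec.n_controls
        pheno = PhenotypeTable(
            pd.DataFrame({"label": [NEGATIVE_LABEL] * n_samples,
                          "condition": condition}, index=idx)
        )
    else:
        labels = [POSITIVE_LABEL] * spec.n_cases + [NEGATIVE_LABEL] * spec.n_controls
        pheno = PhenotypeTable(pd.DataFrame({"label": labels}, index=idx))
    return ExternalCohort(probes, probe_map, pheno, genes[info_idx].tolist())


def probes_from_expression(
    em: ExpressionMatrix,
    probes_per_gene: int = 2,
    probe_noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-express a gene-level matrix as probe-level data.

    Each gene becomes ``probes_per_gene`` probe rows equal to the gene's
    values plus independent Gaussian noise; with zero noise the probe rows
    are identical and collapsing them recovers the input exactly.  Useful to
    check that the external (probe-level) evaluation path reduces to the
    internal one.
    """
    if probes_per_gene < 1:
        raise ValueError("probes_per_gene must be >= 1")
    rng = np.random.default_rng(seed)
    rows, probe_ids, map_rows = [], [], []
    vals = em.values.to_numpy()
    for i, g in enumerate(em.gene_ids):
        for p in range(probes_per_gene):
            pid = f"P_{g}_{p + 1}"
            probe_ids.append(pid)
            map_rows.append((pid, g))
            row = vals[i]
            if probe_noise_sd > 0:
                row = row + rng.normal(0, probe_noise_sd, size=len(row))
            rows.append(row)
    probes = pd.DataFrame(np.array(rows), index=probe_ids, columns=em.sample_ids)
    return probes, pd.DataFrame(map_rows, columns=["probe_id", "gene_id"])


def permute_labels(pheno: PhenotypeTable, seed: int) -> PhenotypeTable:
    """Return a copy of the phenotype with class labels randomly permuted.

    Sample ids and the label multiset are preserved; the permutation is a
    pure function of the seed.
    """
    rng = np.random.default_rng(seed)
    table = pheno.table.copy()
    table["label"] = rng.permutation(table["label"].to_numpy())
    return PhenotypeTable(table)


# ---------------------------------------------------------------------------
# Split plans


@dataclass(frozen=True)
class SplitEntry:
    """One training/holdout split with its nested fold assignments."""

    index: int
    train_ids: tuple[str, ...]
    holdout_ids: tuple[str, ...]
    # outer_folds[i] = (outer_train_ids, outer_test_ids); partitions train_ids
    outer_folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    # inner_folds[i][j] = (inner_train_ids, inner_test_ids); partitions outer_folds[i][0]
    inner_folds: tuple[tuple[tuple[tuple[str, ...], tuple[str, ...]], ...], ...]


@dataclass(frozen=True)
class SplitPlan:
    entries: tuple[SplitEntry, ...]
    k_outer: int
    k_inner: int
    seed: int

    @property
    def n_repeats(self) -> int:
        return len(self.entries)


def _stratified_folds(ids: np.ndarray, y: np.ndarray, k: int, seed: int):
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    out = []
    for tr, te in skf.split(np.zeros(len(ids)), y):
        out.append((tuple(ids[tr]), tuple(ids[te])))
    return tuple(out)


def nested_folds_entry(pheno: PhenotypeTable, k_outer: int, k_inner: int, seed: int) -> SplitEntry:
    """A SplitEntry treating the whole cohort as one training set (no holdout);
    used when feature selection is run outside the split experiment."""
    ids = np.array(pheno.sample_ids)
    y = pheno.y()
    outer = _stratified_folds(ids, y, k_outer, child_seed(seed, "outer", 0))
    inner = tuple(
        _stratified_folds(np.array(o_train), pheno.y(o_train), k_inner,
                          child_seed(seed, "inner", 0, oi))
        for oi, (o_train, _t) in enumerate(outer)
    )
    return SplitEntry(index=0, train_ids=tuple(ids), holdout_ids=(),
                      outer_folds=outer, inner_folds=inner)


def make_split_plan(
    pheno: PhenotypeTable,
    n_repeats: int = 100,
    train_size: int = 120,
    k_outer: int = 5,
    k_inner: int = 5,
    seed: int = 0,
) -> SplitPlan:
    """Build stratified training/holdout splits with nested CV folds.

    Each of ``n_repeats`` entries draws a stratified training set of
    ``train_size`` samples (remainder = holdout), partitions it into
    ``k_outer`` stratified outer folds, and partitions each outer training
    split into ``k_inner`` stratified inner folds.
    """
    n = len(pheno.sample_ids)
    if train_size >= n:
        raise ValueError("train_size must be smaller than the number of samples")
    if k_outer < 2 or k_inner < 2:
        raise ValueError("k_outer and k_inner must be >= 2")
    counts = pheno.labels.value_counts()
    if (counts < max(k_outer, k_inner)).any():
        raise ValueError("each class needs at least as many samples as folds")

    ids = np.array(pheno.sample_ids)
    y = pheno.y()
    entries = []
    for r in range(n_repeats):
        sss = StratifiedShuffleSplit(
            n_splits=1, train_size=train_size, random_state=child_seed(seed, "split", r)
        )
        (tr_idx, ho_idx), = sss.split(np.zeros(n), y)
        train_ids, holdout_ids = ids[tr_idx], ids[ho_idx]
        y_tr = y[tr_idx]
        outer = _stratified_folds(train_ids, y_tr, k_outer, child_seed(seed, "outer", r))
        inner = []
        for oi, (o_train, _o_test) in enumerate(outer):
            o_train_arr = np.array(o_train)
            y_o = pheno.y(o_train_arr)
            inner.append(
                _stratified_folds(o_train_arr, y_o, k_inner, child_seed(seed, "inner", r, oi))
            )
        entries.append(
            SplitEntry(
                index=r,
                train_ids=tuple(train_ids),
                holdout_ids=tuple(holdout_ids),
                outer_folds=outer,
                inner_folds=tuple(inner),
            )
        )
    return SplitPlan(tuple(entries), k_outer=k_outer, k_inner=k_inner, seed=seed)
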