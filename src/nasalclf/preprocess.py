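"""Count filtering, normalization, differential expression and probe collapsing.

Normalization is median-of-ratios size factors followed by
``log2(count / sf + 1)`` — a variance-stabilizing-style transform that keeps
the pipeline's downstream stages (which only need a monotone, roughly
homoskedastic log-scale matrix) independent of any particular DE package.
Differential expression is a Welch t-test on the transformed values with
Benjamini-Hochberg adjustment; genes at FDR <= 0.05 are deemed
differentially expressed.  Development and test cohorts must be processed
through these functions independently: no statistic is shared between them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import (
    NEGATIVE_LABEL,
    POSITIVE_LABEL,
    CountMatrix,
    ExpressionMatrix,
    PhenotypeTable,
)

FDR_THRESHOLD = 0.05


@dataclass(frozen=True)
class FilterParams:
    """Low-count gene filter: drop genes with < min_count counts in at least
    ``min_fraction`` of samples ("at least half" resolves to >= ceil(n/2))."""

    min_count: int = 100
    min_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.min_count < 0:
            raise ValueError("min_count must be >= 0")
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")


def filter_low_counts(cm: CountMatrix, fp: FilterParams = FilterParams()) -> CountMatrix:
    """Drop genes with fewer than ``min_count`` counts in at least
    ``ceil(min_fraction * n_samples)`` samples.  Gene order is preserved."""
    n = cm.n_samples
    if n == 0 or cm.n_genes == 0:
        raise ValueError("empty count matrix")
    cutoff = int(np.ceil(fp.min_fraction * n))
    below = (cm.counts.to_numpy() < fp.min_count).sum(axis=1)
    keep = below < cutoff
    if not keep.any():
        raise ValueError(
            "all genes removed by the low-count filter; lower min_count or min_fraction"
        )
    return CountMatrix(cm.counts.loc[keep])


def compute_size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample s, ``sf_s = median_g(count_gs / geomean_g)`` over genes
    with strictly positive counts in every sample.
    """
    counts = cm.counts.to_numpy(dtype=float)
    eligible = (counts > 0).all(axis=1)
    if not eligible.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; relax filtering first"
        )
    sub = counts[eligible]
    log_geomean = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_geomean[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=cm.sample_ids, name="size_factor")


def vst_transform(
    cm: CountMatrix, sf: pd.Series, role: str = "development"
) -> ExpressionMatrix:
    """Log2 of size-factor-normalized counts plus one: ``log2(c/sf + 1)``."""
    if list(sf.index) != cm.sample_ids:
        raise ValueError("size factors are not aligned to the matrix samples")
    vals = np.log2(cm.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :] + 1.0)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=cm.gene_ids, columns=cm.sample_ids), role=role
    )


def normalize(cm: CountMatrix, role: str = "development") -> ExpressionMatrix:
    """Convenience: size factors + transform in one step."""
    return vst_transform(cm, compute_size_factors(cm), role=role)


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    return multipletests(pvals, method="fdr_bh")[1]


def differential_expression(
    em: ExpressionMatrix, pheno: PhenotypeTable
) -> pd.DataFrame:
    """Per-gene Welch t-test (case vs control) on log2 expression, BH-adjusted.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (mean case −
    mean control), ``pvalue``, ``fdr``, ``direction`` ("over"/"under"/"none")
    and ``degenerate`` (True where both groups had zero variance).  Zero
    pooled variance with equal means gives p = 1; with unequal means the
    smallest positive float, flagged degenerate.
    """
    y = pheno.y(em.sample_ids)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("differential expression needs >= 2 samples per class")
    vals = em.values.to_numpy()
    case, ctrl = vals[:, y == 1], vals[:, y == 0]
    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    # zero variance in both groups: p=1 when means agree, else smallest float
    tiny = np.nextafter(0.0, 1.0)
    p[degenerate & (log2fc == 0)] = 1.0
    p[degenerate & (log2fc != 0)] = tiny
    fdr = benjamini_hochberg(p)
    direction = np.where(log2fc > 0, "over", np.where(log2fc < 0, "under", "none"))
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": p,
            "fdr": fdr,
            "direction": direction,
            "degenerate": degenerate,
        },
        index=pd.Index(em.gene_ids, name="gene_id"),
    )


def significant_genes(de: pd.DataFrame, fdr: float = FDR_THRESHOLD) -> list[str]:
    return de.index[de["fdr"] <= fdr].tolist()


def collapse_probes_to_genes(
    probe_matrix: pd.DataFrame,
    probe_map: pd.DataFrame,
    role: str = "external",
    strict: bool = True,
) -> ExpressionMatrix:
    """Average all probes of a gene into one gene-level expression row.

    ``probe_map`` has columns ``probe_id``/``gene_id``.  Unmapped probes are
    an error when ``strict`` (listed in the message), otherwise skipped.
    """
    mapping = probe_map.set_index("probe_id")["gene_id"]
    unmapped = [p for p in probe_matrix.index if p not in mapping.index]
    if unmapped:
        if strict:
            raise ValueError(f"unmapped probes: {unmapped[:10]}")
        probe_matrix = probe_matrix.drop(index=unmapped)
    genes = mapping.loc[probe_matrix.index]
    collapsed = probe_matrix.groupby(genes.to_numpy()).mean()
    collapsed.index.name = None
    return ExpressionMatrix(collapsed, role=role)
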