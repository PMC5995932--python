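"""Core data containers shared across the pipeline.

Matrices are gene-by-sample pandas DataFrames wrapped in light dataclasses
that enforce the invariants every stage relies on (unique identifiers,
integral non-negative counts, finite expression values).  Expression
matrices carry a *role* tag ("development", "test" or "external") so that
training operations can refuse data that must stay untouched until final
evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

POSITIVE_LABEL = "asthma"
NEGATIVE_LABEL = "no asthma"

#: roles an expression matrix can carry; training ops accept only "development"
ROLES = ("development", "test", "external")


class LeakageError(RuntimeError):
    """Raised when a training operation receives non-development data."""


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} identifiers: {dup[:5]}")


@dataclass
class CountMatrix:
    """Raw integer gene-by-sample counts."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "gene")
        _check_unique(self.counts.columns, "sample")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass
class PhenotypeTable:
    """Per-sample binary class label plus optional covariates.

    The positive class is ``"asthma"``; any covariate columns (age/sex/race)
    ride along untouched.
    """

    table: pd.DataFrame  # indexed by sample_id, column "label" (+ covariates)

    def __post_init__(self) -> None:
        if "label" not in self.table.columns:
            raise ValueError("phenotype table needs a 'label' column")
        _check_unique(self.table.index, "sample")
        bad = set(self.table["label"]) - {POSITIVE_LABEL, NEGATIVE_LABEL}
        if bad:
            raise ValueError(
                f"labels must be '{POSITIVE_LABEL}' or '{NEGATIVE_LABEL}', got {sorted(bad)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]

    def y(self, sample_ids=None) -> np.ndarray:
        """0/1 vector, 1 = asthma, aligned to ``sample_ids`` (or native order)."""
        lab = self.labels if sample_ids is None else self.labels.loc[list(sample_ids)]
        return (lab == POSITIVE_LABEL).to_numpy(dtype=int)

    def subset(self, sample_ids) -> "PhenotypeTable":
        return PhenotypeTable(self.table.loc[list(sample_ids)].copy())

    @property
    def n_positive(self) -> int:
        return int((self.labels == POSITIVE_LABEL).sum())

    @property
    def n_negative(self) -> int:
        return int((self.labels == NEGATIVE_LABEL).sum())


@dataclass
class ExpressionMatrix:
    """Normalized log2-scale gene-by-sample expression with a provenance role."""

    values: pd.DataFrame
    role: str = "development"

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)], role=self.role)

    def require_development(self, op: str) -> None:
        if self.role != "development":
            raise LeakageError(
                f"{op} is a training operation and only accepts development data "
                f"(got role={self.role!r})"
            )
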