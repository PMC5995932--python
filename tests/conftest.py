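"""Shared fixtures: the desk-scale synthetic study and one full discovery run.

The discovery run is expensive (~10 splits of nested-CV RFE), so it is
computed once per session and shared by the integration and acceptance
tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import nasalclf as nc

#: the desk-scale study conditions: 2000 genes, 40 informative at |log2FC|=1.5,
#: development cohort 53 cases / 97 controls
DESK_SPEC = nc.SimulationSpec(seed=1)
PIPELINE_SEED = 42
NULL_SEED = 7


@pytest.fixture(scope="session")
def dev_cohort():
    return nc.generate_cohort(DESK_SPEC)


@pytest.fixture(scope="session")
def dev_em(dev_cohort):
    filtered = nc.filter_low_counts(dev_cohort.counts)
    return nc.normalize(filtered, role="development")


@pytest.fixture(scope="session")
def test_cohort():
    return nc.generate_test_cohort(DESK_SPEC)  # 13 cases / 27 controls


@pytest.fixture(scope="session")
def test_em(test_cohort):
    return nc.normalize(test_cohort.counts, role="test")


@pytest.fixture(scope="session")
def discovery(dev_cohort):
    """Full desk-preset discovery: 10 splits x 8 combos, Friedman-Nemenyi,
    representative selection and the final development-set refit."""
    return nc.discover_classifier(
        dev_cohort.counts, dev_cohort.phenotype, nc.PipelineConfig(),
        seed=PIPELINE_SEED,
    )


@pytest.fixture(scope="session")
def null_distribution(dev_cohort, test_em, test_cohort, discovery):
    """20 permutation-null pipelines evaluated on the untouched test set."""
    real = nc.evaluate_model(
        discovery.final_model, test_em, test_cohort.phenotype
    ).metrics.f_pos
    return nc.permutation_null(
        dev_cohort.counts, dev_cohort.phenotype, test_em, test_cohort.phenotype,
        nc.PipelineConfig(), n_perm=20, seed=NULL_SEED, real_value=real,
    )


def toy_expression(X: np.ndarray, y: np.ndarray, role: str = "development"):
    """Wrap a samples-by-genes array + 0/1 labels into package containers."""
    n, p = X.shape
    samples = [f"s{i:03d}" for i in range(n)]
    genes = [f"g{j:03d}" for j in range(p)]
    em = nc.ExpressionMatrix(
        pd.DataFrame(X.T, index=genes, columns=samples), role=role
    )
    pheno = nc.PhenotypeTable(
        pd.DataFrame(
            {"label": np.where(y == 1, nc.POSITIVE_LABEL, nc.NEGATIVE_LABEL)},
            index=pd.Index(samples, name="sample_id"),
        )
    )
    return em, pheno
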