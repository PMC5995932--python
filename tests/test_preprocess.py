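"""Count filtering, size factors, transformation, DE and probe collapsing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import nasalclf as nc
from nasalclf.preprocess import FilterParams, benjamini_hochberg


def _cm(rows: dict[str, list[int]], samples=None) -> nc.CountMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = samples or [f"s{i}" for i in range(df.shape[1])]
    return nc.CountMatrix(df)


class TestFilterLowCounts:
    @pytest.mark.parametrize(
        "counts,kept",
        [
            ([100, 100, 100, 100], True),   # no sample below the threshold
            ([99, 99, 100, 100], False),    # 2 of 4 below, 2 >= ceil(0.5*4)
            ([99, 100, 100, 100], True),    # 1 below < 2
        ],
    )
    def test_rule_on_fixtures(self, counts, kept):
        cm = _cm({"g1": counts, "keepme": [1000] * 4})
        out = nc.filter_low_counts(cm, FilterParams(100, 0.5))
        assert ("g1" in out.gene_ids) is kept

    def test_odd_sample_count_uses_ceiling(self):
        # 3 samples: dropped iff >= ceil(1.5) = 2 samples below
        cm = _cm({"one_low": [99, 100, 100], "two_low": [99, 99, 100],
                  "anchor": [500, 500, 500]})
        out = nc.filter_low_counts(cm)
        assert "one_low" in out.gene_ids and "two_low" not in out.gene_ids

    def test_idempotent_and_subset(self):
        c = nc.generate_cohort(nc.SimulationSpec(n_genes=300, seed=8))
        once = nc.filter_low_counts(c.counts)
        twice = nc.filter_low_counts(once)
        assert set(once.gene_ids) <= set(c.counts.gene_ids)
        pd.testing.assert_frame_equal(once.counts, twice.counts)
        # gene order preserved
        order = [g for g in c.counts.gene_ids if g in set(once.gene_ids)]
        assert once.gene_ids == order

    def test_all_removed_is_explicit_error(self):
        cm = _cm({"g1": [0, 0], "g2": [1, 1]})
        with pytest.raises(ValueError, match="min_count"):
            nc.filter_low_counts(cm, FilterParams(100, 0.5))


class TestSizeFactors:
    def test_two_sample_doubling_closed_form(self):
        # sample A = 2x sample B for every gene -> sf (sqrt2, 1/sqrt2)
        cm = _cm({"g1": [20, 10], "g2": [40, 20], "g3": [6, 3]})
        sf = nc.compute_size_factors(cm)
        assert np.allclose(sf.to_numpy(), [np.sqrt(2), 1 / np.sqrt(2)])

    def test_identical_samples_unit_factors(self):
        cm = _cm({"g1": [10, 10, 10], "g2": [7, 7, 7]})
        assert np.allclose(nc.compute_size_factors(cm).to_numpy(), 1.0)

    def test_invariant_to_gene_order(self):
        c = nc.generate_cohort(nc.SimulationSpec(n_genes=50, seed=3))
        sf = nc.compute_size_factors(c.counts)
        shuffled = nc.CountMatrix(c.counts.counts.sample(frac=1, random_state=0))
        sf2 = nc.compute_size_factors(shuffled)
        pd.testing.assert_series_equal(sf, sf2)

    def test_scale_equivariance_of_factor_ratios(self):
        # scaling one sample by c rescales the gene-wise geometric means by
        # c^(1/n), so the invariant is on size-factor ratios: sf_s1/sf_s0
        # gains exactly a factor c
        cm = _cm({"g1": [10, 20, 30], "g2": [40, 8, 12], "g3": [5, 5, 5]})
        sf = nc.compute_size_factors(cm)
        scaled = cm.counts.copy()
        scaled["s1"] = scaled["s1"] * 3
        sf2 = nc.compute_size_factors(nc.CountMatrix(scaled))
        assert np.isclose(sf2["s1"] / sf2["s0"], 3 * sf["s1"] / sf["s0"])
        assert np.isclose(sf2["s1"], 3 ** (2 / 3) * sf["s1"])

    def test_no_eligible_gene_error(self):
        cm = _cm({"g1": [0, 5], "g2": [5, 0]})
        with pytest.raises(ValueError, match="nonzero"):
            nc.compute_size_factors(cm)


class TestVstTransform:
    def test_known_values(self):
        cm = _cm({"g1": [0, 127]})
        sf = pd.Series([1.0, 1.0], index=cm.sample_ids)
        em = nc.vst_transform(cm, sf)
        assert em.values.loc["g1", "s0"] == 0.0          # log2(0/1 + 1)
        assert em.values.loc["g1", "s1"] == 7.0          # log2(128)

    def test_misaligned_size_factors_error(self):
        cm = _cm({"g1": [1, 2]})
        sf = pd.Series([1.0, 1.0], index=["x", "y"])
        with pytest.raises(ValueError, match="aligned"):
            nc.vst_transform(cm, sf)

    def test_doubling_sample_shifts_transform_by_constant(self):
        # doubling one of n samples scales its size factor by 2^((n-1)/n) and
        # the others' by 2^(-1/n), so at large counts the whole transformed
        # matrix shifts by the constant log2(2^(1/n)) — here 0.5 — with the
        # gene-by-sample structure untouched (up to the +1 pseudocount)
        cm = _cm({"g1": [1000, 2000], "g2": [4000, 500], "g3": [800, 800]})
        em = nc.normalize(cm)
        doubled = cm.counts.copy()
        doubled["s0"] = doubled["s0"] * 2
        em2 = nc.normalize(nc.CountMatrix(doubled))
        assert np.allclose(em2.values, em.values + 0.5, atol=2e-3)


class TestDifferentialExpression:
    def test_identical_groups_give_null_result(self):
        X = np.ones((10, 3))
        X[:, 0] = np.arange(10)  # constant-difference gene across all samples
        em = nc.ExpressionMatrix(pd.DataFrame(
            X.T, index=["gA", "gB", "gC"], columns=[f"s{i}" for i in range(10)]))
        labels = [nc.POSITIVE_LABEL] * 5 + [nc.NEGATIVE_LABEL] * 5
        pheno = nc.PhenotypeTable(pd.DataFrame(
            {"label": labels}, index=pd.Index(em.sample_ids, name="sample_id")))
        de = nc.differential_expression(em, pheno)
        # gB/gC constant in both groups -> log2FC 0, p 1 (documented convention)
        assert de.loc["gB", "log2fc"] == 0 and de.loc["gB", "pvalue"] == 1.0
        assert de.loc["gB", "degenerate"]

    def test_single_class_error(self):
        em, pheno = _toy_em_all_positive()
        with pytest.raises(ValueError):
            nc.differential_expression(em, pheno)

    def test_fdr_at_least_raw_p(self):
        c = nc.generate_cohort(nc.SimulationSpec(n_genes=200, seed=12))
        de = nc.differential_expression(nc.normalize(c.counts), c.phenotype)
        assert (de["fdr"] >= de["pvalue"] - 1e-12).all()
        assert de["fdr"].between(0, 1).all()
        up = de["log2fc"] > 0
        assert (de.loc[up, "direction"] == "over").all()


def _toy_em_all_positive():
    em = nc.ExpressionMatrix(pd.DataFrame(
        [[1.0, 2.0, 3.0]], index=["g"], columns=["a", "b", "c"]))
    pheno = nc.PhenotypeTable(pd.DataFrame(
        {"label": [nc.POSITIVE_LABEL] * 3},
        index=pd.Index(["a", "b", "c"], name="sample_id")))
    return em, pheno


def bh_bruteforce(p):
    """Step-up BH reference: independent of the implementation under test."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBenjaminiHochberg:
    def test_equal_pvalues_unchanged(self):
        assert np.allclose(benjamini_hochberg(np.full(7, 0.01)), 0.01)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=100))
    @settings(max_examples=200, deadline=None)
    def test_matches_bruteforce_step_up(self, pvals):
        p = np.array(pvals)
        assert np.allclose(benjamini_hochberg(p), bh_bruteforce(p), atol=1e-12)


class TestCollapseProbes:
    def test_mean_single_and_idempotent(self):
        probes = pd.DataFrame(
            {"x": [1.0, 3.0, 5.0, 2.0, 2.0, 2.0]},
            index=["p1", "p2", "p3", "q1", "q2", "q3"],
        )
        pm = pd.DataFrame({
            "probe_id": ["p1", "p2", "p3", "q1", "q2", "q3"],
            "gene_id": ["gA", "gA", "gB", "gC", "gC", "gC"],
        })
        em = nc.collapse_probes_to_genes(probes, pm)
        assert em.values.loc["gA", "x"] == 2.0       # mean of (1, 3)
        assert em.values.loc["gB", "x"] == 5.0       # single probe passthrough
        assert em.values.loc["gC", "x"] == 2.0       # (a, a, a) -> a

    def test_unmapped_probe_error_lists_probe(self):
        probes = pd.DataFrame({"x": [1.0]}, index=["orphan"])
        pm = pd.DataFrame({"probe_id": ["p1"], "gene_id": ["g"]})
        with pytest.raises(ValueError, match="orphan"):
            nc.collapse_probes_to_genes(probes, pm)
        em = nc.collapse_probes_to_genes(probes, pm, strict=False)
        assert em.values.empty
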