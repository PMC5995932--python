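"""Friedman-Nemenyi comparison, combo/representative selection, final fit."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import friedmanchisquare, rankdata

import nasalclf as nc
from nasalclf.selection import (
    ComboScore,
    friedman_test,
    nemenyi_cd,
    select_best_combo,
    select_representative,
)

from conftest import PIPELINE_SEED


def friedman_bruteforce(scores: np.ndarray) -> float:
    """Independent rank-based computation: explicit per-row ranks, no reuse of
    the implementation's formula code path."""
    n, k = scores.shape
    ranks = np.array([rankdata(-row, method="average") for row in scores])
    rj = ranks.mean(axis=0)
    return 12.0 * n / (k * (k + 1)) * np.sum(rj**2) - 3.0 * n * (k + 1)


class TestFriedman:
    def test_three_method_fixture(self):
        # one method always best, one middle, one worst over N=10 splits
        scores = pd.DataFrame(
            np.tile([3.0, 2.0, 1.0], (10, 1)), columns=["a", "b", "c"]
        )
        stat, p, mean_ranks = friedman_test(scores)
        assert np.isclose(stat, 20.0)
        assert list(mean_ranks.round(6)) == [1.0, 2.0, 3.0]
        assert p < 1e-4

    def test_constant_scores(self):
        scores = pd.DataFrame(np.ones((5, 4)))
        stat, p, _ = friedman_test(scores)
        assert stat == 0.0 and p == 1.0

    def test_matches_bruteforce_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            scores = rng.random((5, 4))
            stat, _, _ = friedman_test(pd.DataFrame(scores))
            assert np.isclose(stat, friedman_bruteforce(scores))

    def test_matches_scipy_without_ties(self):
        rng = np.random.default_rng(1)
        scores = rng.random((12, 5))
        stat, p, _ = friedman_test(pd.DataFrame(scores))
        ref_stat, ref_p = friedmanchisquare(*scores.T)
        assert np.isclose(stat, ref_stat) and np.isclose(p, ref_p)

    def test_rank_sums_and_monotone_invariance(self):
        rng = np.random.default_rng(2)
        scores = pd.DataFrame(rng.random((8, 6)))
        stat, _, mean_ranks = friedman_test(scores)
        assert np.isclose(mean_ranks.sum(), 6 * 7 / 2)
        stat2, _, _ = friedman_test(np.exp(5 * scores))  # strictly monotone
        assert np.isclose(stat, stat2)

    def test_too_small_inputs_error(self):
        with pytest.raises(ValueError):
            friedman_test(pd.DataFrame(np.ones((1, 3))))


class TestNemenyi:
    def test_tabulated_critical_difference(self):
        assert np.isclose(nemenyi_cd(8, 100, 0.05), 1.050, atol=1e-3)

    def test_two_methods_positive_and_monotone_in_n(self):
        cds = [nemenyi_cd(2, n) for n in (10, 100, 1000)]
        assert all(c > 0 for c in cds)
        assert cds[0] > cds[1] > cds[2]

    def test_untabulated_k_error(self):
        with pytest.raises(ValueError):
            nemenyi_cd(12, 100)


def _result_from_tables(adapted, raw_f, sizes, models=None):
    return nc.ExperimentResult(
        adapted=adapted, raw_f=raw_f, panel_sizes=sizes,
        models=models or {}, gene_sets={},
    )


class TestSelectBestCombo:
    def test_dominating_combo_wins(self):
        adapted = pd.DataFrame({"x": [0.9, 0.8, 0.95], "y": [0.3, 0.2, 0.1]})
        res = _result_from_tables(adapted, adapted, adapted * 0 + 1)
        fnr = nc.friedman_nemenyi(adapted)
        assert select_best_combo(res, fnr) == "x"

    def test_tied_columns_deterministic(self):
        col = [0.5, 0.6, 0.7, 0.4]
        adapted = pd.DataFrame({"x": col, "y": col})
        raw = pd.DataFrame({"x": col, "y": col})
        sizes = pd.DataFrame({"x": [2] * 4, "y": [4] * 4})
        res = _result_from_tables(adapted, raw, sizes)
        fnr = nc.friedman_nemenyi(adapted)
        # equal ranks and F: the smaller mean panel size breaks the tie
        assert select_best_combo(res, fnr) == "x"


class TestSelectRepresentative:
    def _models(self, combos, splits):
        class Stub:
            def __init__(self, split, combo):
                self.genes = ("g1",)
                self.threshold = 0.5
                self.provenance = {"split_index": split, "combo": combo}
        return {(s, c): Stub(s, c) for c in combos for s in splits}

    def test_unique_maximum(self):
        combos = ["LR-RFE & Logistic", "LR-RFE & SVM-Linear",
                  "LR-RFE & AdaBoost", "LR-RFE & RandomForest"]
        raw = pd.DataFrame(
            {c: [0.5, 0.9 if c.endswith("Logistic") else 0.4, 0.6] for c in combos}
        )
        res = _result_from_tables(raw / 2, raw, raw * 0 + 2,
                                  models=self._models(combos, range(3)))
        rep = select_representative(res, "LR-RFE & Logistic")
        assert rep.split_index == 1

    def test_tie_resolved_by_cross_classifier_average(self):
        combos = ["LR-RFE & Logistic", "LR-RFE & SVM-Linear",
                  "LR-RFE & AdaBoost", "LR-RFE & RandomForest"]
        raw = pd.DataFrame({c: [1.0, 1.0, 0.5] for c in combos})
        # split 1's gene set does better on average across the 4 classifiers
        raw.loc[0, "LR-RFE & AdaBoost"] = 0.6
        res = _result_from_tables(raw, raw, raw * 0 + 2,
                                  models=self._models(combos, range(3)))
        rep = select_representative(res, "LR-RFE & Logistic")
        assert rep.split_index == 1

    def test_full_tie_falls_back_to_lowest_split(self):
        combos = ["LR-RFE & Logistic"]
        raw = pd.DataFrame({c: [0.7, 0.7, 0.7] for c in combos})
        res = _result_from_tables(raw, raw, raw * 0 + 3,
                                  models=self._models(combos, range(3)))
        assert select_representative(res, combos[0]).split_index == 0


class TestComboScore:
    def test_adapted_score_arithmetic(self):
        s = ComboScore(split_index=0, combo="x", f_pos=0.8, panel_size=4)
        assert s.adapted == 0.2

    def test_parsimony_monotonicity(self):
        fs = [ComboScore(0, "x", 0.8, g).adapted for g in (1, 2, 5, 10)]
        assert all(a > b for a, b in zip(fs, fs[1:]))


class TestExperimentIntegration:
    def test_score_matrix_shape_and_consistency(self, discovery):
        exp = discovery.experiment
        assert exp.adapted.shape == (10, 8)
        # adapted = F / size wherever a model exists
        mask = exp.adapted.notna()
        np.testing.assert_allclose(
            exp.adapted[mask].to_numpy(dtype=float),
            (exp.raw_f[mask] / exp.panel_sizes[mask]).to_numpy(dtype=float),
        )
        # recorded failures explain every missing cell
        failed_cells = {(s, c) for s, c, _ in exp.failures}
        missing = {(s, c) for s, c in zip(*np.where(~mask.to_numpy()))
                   for s, c in [(mask.index[s], mask.columns[c])]}
        assert missing == failed_cells

    def test_strong_signal_split_all_combos_accurate(self, discovery):
        complete = discovery.experiment.raw_f.dropna(axis=0)
        assert not complete.empty
        assert (complete.min(axis=1) >= 0.8).all()

    def test_representative_comes_from_best_combo(self, discovery):
        rep = discovery.representative
        assert rep.combo == discovery.best_combo
        assert rep.model.provenance["split_index"] == rep.split_index

    def test_final_model_panel_and_threshold_carried(self, discovery):
        rep = discovery.representative
        final = discovery.final_model
        assert final.genes == rep.genes
        assert final.threshold == rep.threshold
        assert final.provenance.get("final") is True

    def test_final_model_fits_development_set(self, discovery, dev_cohort):
        preds = discovery.final_model.predict(discovery.em_dev)
        y = dev_cohort.phenotype.y(preds.sample_ids)
        f_dev = nc.f_measure(y, preds.calls)
        rep_f = discovery.experiment.raw_f.loc[
            discovery.representative.split_index, discovery.best_combo
        ]
        assert f_dev >= rep_f - 0.1

    def test_checkpoint_resume_reproduces_scores(self, dev_cohort, tmp_path):
        cfg = nc.PipelineConfig(n_repeats=2)
        filtered = nc.filter_low_counts(dev_cohort.counts)
        em = nc.normalize(filtered)
        plan = nc.make_split_plan(dev_cohort.phenotype, n_repeats=2,
                                  train_size=120, k_outer=3, k_inner=3, seed=4)
        ck = str(tmp_path / "ck")
        first = nc.run_experiment(em, dev_cohort.phenotype, plan, cfg,
                                  seed=5, checkpoint_dir=ck)
        resumed = nc.run_experiment(em, dev_cohort.phenotype, plan, cfg,
                                    seed=5, checkpoint_dir=ck)
        pd.testing.assert_frame_equal(first.adapted, resumed.adapted)
        pd.testing.assert_frame_equal(first.raw_f, resumed.raw_f)
        combo = first.adapted.columns[0]
        if (0, combo) in first.models and (0, combo) in resumed.models:
            a, b = first.models[(0, combo)], resumed.models[(0, combo)]
            np.testing.assert_array_equal(
                a.predict(em).probabilities, b.predict(em).probabilities
            )


class TestFixedGeneSetPipeline:
    def test_planted_panel_performs(self, dev_cohort, dev_em):
        planted = [g for g in dev_cohort.informative_genes
                   if g in set(dev_em.gene_ids)]
        plan = nc.make_split_plan(dev_cohort.phenotype, n_repeats=3,
                                  train_size=120, k_outer=3, k_inner=3, seed=9)
        final, f_table = nc.fixed_geneset_pipeline(
            dev_em, dev_cohort.phenotype, planted, plan, seed=11
        )
        assert set(final.genes) == set(planted)
        assert f_table.shape == (3, 4)
        assert f_table.mean().max() >= 0.8

    def test_singleton_gene_set_completes(self, dev_cohort, dev_em):
        plan = nc.make_split_plan(dev_cohort.phenotype, n_repeats=2,
                                  train_size=120, k_outer=3, k_inner=3, seed=9)
        final, _ = nc.fixed_geneset_pipeline(
            dev_em, dev_cohort.phenotype, [dev_em.gene_ids[0]], plan, seed=1
        )
        assert final.genes == (dev_em.gene_ids[0],)

    def test_absent_gene_listed_in_error(self, dev_cohort, dev_em):
        plan = nc.make_split_plan(dev_cohort.phenotype, n_repeats=2,
                                  train_size=120, k_outer=3, k_inner=3, seed=9)
        with pytest.raises(ValueError, match="NOPE"):
            nc.fixed_geneset_pipeline(dev_em, dev_cohort.phenotype, ["NOPE"],
                                      plan, seed=1)
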