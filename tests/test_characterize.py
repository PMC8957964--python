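import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylbmi import DMBMIModel
from methylbmi.characterize import (ConfigurationError, PairingError,
                                    correlate_features_with_score,
                                    correlate_methylation_expression,
                                    paired_dmp_test,
                                    summarize_predictor_distribution)
from methylbmi.containers import AnnotationError

from conftest import make_annotation, make_beta


def _model(probes):
    return DMBMIModel(intercept=0.0,
                      coefficients={p: 1.0 for p in probes},
                      lambda_selected=0.1, cv_folds=10, seed=0)


class TestDistributionSummary:
    def test_direct_counts(self):
        ann = make_annotation(["a", "b", "c", "d"],
                              region=["Body", "Body", "TSS200", "IGR"])
        summary = summarize_predictor_distribution(_model(["a", "b", "c", "d"]),
                                                   ann)
        table = summary["region_group"].set_index("category")
        assert table.loc["Body", "proportion"] == pytest.approx(0.5)
        assert table.loc["TSS200", "proportion"] == pytest.approx(0.25)
        assert table.loc["IGR", "proportion"] == pytest.approx(0.25)

    def test_zero_count_categories_reported(self):
        ann = make_annotation(["a", "b"], cgi=["island", "shore"])
        summary = summarize_predictor_distribution(_model(["a"]), ann)
        table = summary["cgi_relation"].set_index("category")
        assert table.loc["shore", "count"] == 0

    def test_empty_model_warns(self):
        ann = make_annotation(["a"])
        summary = summarize_predictor_distribution(_model([]), ann)
        assert summary.warning is not None
        assert summary.n_probes == 0

    def test_proportions_sum_to_one(self, small_cohort):
        cohort, _ = small_cohort
        probes = cohort.beta.probe_ids[:100]
        summary = summarize_predictor_distribution(_model(probes),
                                                   cohort.annotation)
        for axis in ("chr", "region_group", "cgi_relation"):
            assert summary[axis]["proportion"].sum() == pytest.approx(1.0,
                                                                      abs=1e-12)

    def test_matches_independent_tally(self, small_cohort):
        cohort, _ = small_cohort
        probes = cohort.beta.probe_ids[:100]
        summary = summarize_predictor_distribution(_model(probes),
                                                   cohort.annotation)
        ann = cohort.annotation.table.set_index("probe_id")
        oracle = ann.loc[probes, "region_group"].value_counts()
        table = summary["region_group"].set_index("category")["count"]
        for cat, n in oracle.items():
            assert table[cat] == n

    def test_unannotated_probe_raises(self):
        ann = make_annotation(["a"])
        with pytest.raises(AnnotationError):
            summarize_predictor_distribution(_model(["a", "zz"]), ann)


class TestPairedDMP:
    def _pairs(self, n):
        return {f"T{i}": f"N{i}" for i in range(n)}

    def test_identical_matrices_all_null(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0.2, 0.8, (6, 10))
        tumor = make_beta(X, sample_prefix="T")
        adjacent = make_beta(X, sample_prefix="N")
        results = paired_dmp_test(tumor, adjacent, self._pairs(10))
        assert all(r.direction == "ns" for r in results)
        assert all(np.isnan(r.t_stat) for r in results)  # zero-variance diffs

    def test_shifted_probe_flagged_hyper_with_closed_form_t(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0.3, 0.6, (5, 10))
        tumor_vals = base + rng.normal(0, 0.005, (5, 10))
        tumor_vals[0] += 0.2  # one truly hyper-methylated probe
        tumor = make_beta(np.clip(tumor_vals, 0, 1), sample_prefix="T")
        adjacent = make_beta(base, sample_prefix="N")
        results = paired_dmp_test(tumor, adjacent, self._pairs(10))
        r0 = results[0]
        assert r0.direction == "hyper"
        d = tumor.values[0] - adjacent.values[0]
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(10))
        assert r0.t_stat == pytest.approx(t_oracle, abs=1e-10)
        p_oracle = 2 * stats.t.sf(abs(t_oracle), df=9)
        assert r0.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_bh_step_up_hand_example(self):
        # p = (.01,.02,.03,.04), m=4 -> q all .04 by the step-up rule
        rng = np.random.default_rng(2)
        n = 40
        targets = [0.01, 0.02, 0.03, 0.04]
        # build 4 probes whose paired-t p-values hit the targets exactly by
        # scaling a fixed difference pattern
        d0 = rng.normal(0, 1, n)
        d0 = (d0 - d0.mean()) / d0.std(ddof=1)  # mean 0, sd 1
        rows_t, rows_a = [], []
        for p_target in targets:
            t_needed = stats.t.isf(p_target / 2, df=n - 1)
            d = d0 + t_needed / np.sqrt(n)   # gives exactly t_needed
            rows_a.append(np.full(n, 0.4))
            rows_t.append(0.4 + d * 0.05)
        tumor = make_beta(np.clip(np.vstack(rows_t), 0, 1), sample_prefix="T")
        adjacent = make_beta(np.vstack(rows_a), sample_prefix="N")
        results = paired_dmp_test(tumor, adjacent, self._pairs(n))
        for r, p_target in zip(results, targets):
            assert r.p_value == pytest.approx(p_target, abs=1e-9)
            assert r.q_value == pytest.approx(0.04, abs=1e-9)

    def test_too_few_pairs_rejected(self):
        X = np.full((2, 2), 0.5)
        tumor = make_beta(X, sample_prefix="T")
        adjacent = make_beta(X, sample_prefix="N")
        with pytest.raises(PairingError):
            paired_dmp_test(tumor, adjacent, self._pairs(2))

    def test_unmatched_sample_rejected(self):
        X = np.full((2, 4), 0.5)
        tumor = make_beta(X, sample_prefix="T")
        adjacent = make_beta(X, sample_prefix="N")
        pairs = self._pairs(4)
        pairs["T3"] = "MISSING"
        with pytest.raises(PairingError, match="MISSING"):
            paired_dmp_test(tumor, adjacent, pairs)


class TestCorrelationScreen:
    def test_perfect_monotone_flagged(self):
        score = np.array([1.0, 2, 3, 4, 5])
        recs = correlate_features_with_score(score[None, :], score)
        assert recs[0].r == pytest.approx(1.0)
        assert recs[0].flagged

    def test_antitone_flagged(self):
        score = np.array([1.0, 2, 3, 4, 5])
        recs = correlate_features_with_score(-score[None, :], score)
        assert recs[0].r == pytest.approx(-1.0)
        assert recs[0].flagged

    def test_r_exactly_threshold_not_flagged(self):
        # ranks (1..5) vs (4,2,1,3,5): sum d^2 = 14, r = 1 - 6*14/120 = 0.3
        feature = np.array([1.0, 2, 3, 4, 5])
        score = np.array([40.0, 20, 10, 30, 50])
        recs = correlate_features_with_score(feature[None, :], score)
        assert recs[0].r == pytest.approx(0.3, abs=1e-12)
        assert not recs[0].flagged

    def test_constant_feature_emitted_with_note(self):
        score = np.array([1.0, 2, 3, 4])
        recs = correlate_features_with_score(np.full((1, 4), 0.5), score)
        assert len(recs) == 1
        assert np.isnan(recs[0].r)
        assert not recs[0].flagged
        assert "constant" in recs[0].note

    def test_sample_reorder_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (4, 30))
        score = rng.uniform(20, 40, 30)
        perm = rng.permutation(30)
        r1 = [r.r for r in correlate_features_with_score(X, score)]
        r2 = [r.r for r in correlate_features_with_score(X[:, perm],
                                                         score[perm])]
        np.testing.assert_allclose(r1, r2, atol=1e-12)


class TestMethylationExpression:
    def test_constructed_negative_coupling(self):
        rng = np.random.default_rng(4)
        beta = make_beta(rng.uniform(0, 1, (3, 25)))
        expr = pd.DataFrame(10.0 - 5.0 * beta.values,
                            index=["g0", "g1", "g2"],
                            columns=beta.sample_ids)
        mapping = {"cg0": "g0", "cg1": "g1", "cg2": "g2"}
        records, skipped = correlate_methylation_expression(beta, expr, mapping)
        assert not skipped
        assert all(r.r < 0 and r.flagged for r in records)

    def test_unmapped_probe_in_skip_log(self):
        rng = np.random.default_rng(5)
        beta = make_beta(rng.uniform(0, 1, (2, 10)))
        expr = pd.DataFrame(rng.normal(8, 1, (1, 10)), index=["g0"],
                            columns=beta.sample_ids)
        records, skipped = correlate_methylation_expression(
            beta, expr, {"cg0": "g0"})
        assert [r.feature_id for r in records] == ["cg0"]
        assert any("cg1" in s for s in skipped)

    def test_empty_mapping_rejected(self):
        beta = make_beta(np.full((1, 5), 0.5))
        expr = pd.DataFrame(np.zeros((1, 5)), index=["g"],
                            columns=beta.sample_ids)
        with pytest.raises(ConfigurationError):
            correlate_methylation_expression(beta, expr, {})

    def test_generator_promoter_genes_more_negative(self, small_cohort):
        cohort, _ = small_cohort
        ann = cohort.annotation.table
        promoter = ann[ann["region_group"].isin(["TSS200", "TSS1500"])
                       & (ann["gene"] != "")]["probe_id"].tolist()
        decoupled = ann[(ann["region_group"] == "Body")
                        & (ann["gene"] != "")]["probe_id"].tolist()
        mapping = cohort.probe_gene_map
        beta_p = cohort.beta.subset_probes(promoter)
        beta_d = cohort.beta.subset_probes(decoupled)
        rec_p, _ = correlate_methylation_expression(beta_p, cohort.expression,
                                                    mapping)
        rec_d, _ = correlate_methylation_expression(beta_d, cohort.expression,
                                                    mapping)
        frac_p = np.mean([r.flagged for r in rec_p])
        frac_d = np.mean([r.flagged for r in rec_d])
        assert frac_p > frac_d
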