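import numpy as np
import pandas as pd
import pytest

from methylbmi.scores import (AlignmentError, APM_GENES, CoverageError,
                              IFNG_GENES, NeedsGeneListError, SignatureSet,
                              associate_scores, build_score_table,
                              builtin_signatures, compute_tmb, get_signature,
                              score_signature)


class TestTMB:
    def test_zero_and_unit_cases(self):
        np.testing.assert_array_equal(compute_tmb(np.array([0])), [0.0])
        assert compute_tmb(np.array([38]))[0] == 1.0

    def test_arithmetic(self):
        assert compute_tmb(np.array([95]))[0] == pytest.approx(2.5)

    def test_linearity_and_exome_scaling(self):
        counts = np.array([0, 10, 38, 95, 200])
        base = compute_tmb(counts)
        np.testing.assert_allclose(compute_tmb(2 * counts), 2 * base)
        np.testing.assert_allclose(compute_tmb(counts, exome_mb=76.0), base / 2)

    def test_series_round_trip(self):
        s = pd.Series([19, 38], index=["a", "b"])
        tmb = compute_tmb(s)
        assert isinstance(tmb, pd.Series)
        assert tmb["a"] == 0.5

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_tmb(np.array([-1]))


class TestSignatures:
    def test_ifng_membership(self):
        sig = get_signature("IFNG")
        assert set(sig.gene_symbols) == {"IFNG", "STAT1", "IDO1", "CXCL9",
                                         "CXCL10", "HLA-DRA"}
        assert len(sig.gene_symbols) == 6

    def test_apm_membership(self):
        sig = get_signature("APM")
        assert len(sig.gene_symbols) == 18
        for g in ("HLA-A", "HLA-B", "HLA-C", "TAP1", "TAP2", "B2M"):
            assert g in sig.gene_symbols

    def test_ifng_gs_requires_gene_list(self):
        with pytest.raises(NeedsGeneListError):
            get_signature("IFNG.GS")
        sig = get_signature("IFNG.GS", genes=["A", "B"])
        assert sig.gene_symbols == ("A", "B")

    def test_builtin_list(self):
        names = [s.name for s in builtin_signatures()]
        assert names == ["IFNG", "APM"]
        names = [s.name for s in builtin_signatures(ifng_gs_genes=["A"])]
        assert "IFNG.GS" in names

    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError):
            SignatureSet("bad", ("A", "A"))


class TestScoreSignature:
    def _expr(self, values, genes, samples=None):
        samples = samples or [f"S{i}" for i in range(values.shape[1])]
        return pd.DataFrame(values, index=genes, columns=samples)

    def test_constant_genes(self):
        expr = self._expr(np.full((3, 4), 7.0), ["A", "B", "C"])
        score, meta = score_signature(expr, SignatureSet("s", ("A", "B", "C")))
        np.testing.assert_allclose(score, 7.0)
        assert meta["missing_genes"] == []

    def test_singleton_signature(self):
        rng = np.random.default_rng(0)
        expr = self._expr(rng.normal(8, 1, (2, 5)), ["A", "B"])
        score, _ = score_signature(expr, SignatureSet("s", ("B",)))
        np.testing.assert_allclose(score.to_numpy(), expr.loc["B"].to_numpy())

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(20)]
        expr = self._expr(rng.normal(8, 2, (20, 10)), genes)
        sig = SignatureSet("s", tuple(genes[3:8]))
        score, _ = score_signature(expr, sig)
        oracle = np.array([
            np.mean([expr.loc[g, s] for g in sig.gene_symbols])
            for s in expr.columns])
        np.testing.assert_allclose(score.to_numpy(), oracle, atol=1e-12)

    def test_gene_order_and_extra_rows_irrelevant(self):
        rng = np.random.default_rng(2)
        genes = ["A", "B", "C", "D"]
        expr = self._expr(rng.normal(8, 1, (4, 6)), genes)
        s1, _ = score_signature(expr, SignatureSet("s", ("A", "C")))
        s2, _ = score_signature(expr.iloc[::-1], SignatureSet("s", ("C", "A")))
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy())

    def test_missing_genes_reported(self):
        expr = self._expr(np.full((1, 3), 5.0), ["A"])
        score, meta = score_signature(expr, SignatureSet("s", ("A", "ZZ")))
        assert meta["missing_genes"] == ["ZZ"]
        np.testing.assert_allclose(score, 5.0)

    def test_zero_coverage_rejected(self):
        expr = self._expr(np.full((1, 3), 5.0), ["A"])
        with pytest.raises(CoverageError):
            score_signature(expr, SignatureSet("s", ("X", "Y")))


class TestAssociateScores:
    def test_identical_column_r_one(self):
        idx = [f"S{i}" for i in range(20)]
        dmbmi = pd.Series(np.linspace(20, 40, 20), index=idx)
        scores = pd.DataFrame({"same": dmbmi})
        recs = associate_scores(dmbmi, scores)
        assert recs[0].r == pytest.approx(1.0)
        assert recs[0].extra["n_overlap"] == 20

    def test_permuted_column_near_zero(self):
        rng = np.random.default_rng(3)
        idx = [f"S{i}" for i in range(500)]
        dmbmi = pd.Series(rng.uniform(20, 40, 500), index=idx)
        scores = pd.DataFrame({"null": rng.permutation(dmbmi.to_numpy())},
                              index=idx)
        recs = associate_scores(dmbmi, scores)
        assert abs(recs[0].r) < 0.15

    def test_overlap_size_is_set_intersection(self):
        rng = np.random.default_rng(4)
        idx = [f"S{i}" for i in range(30)]
        dmbmi = pd.Series(rng.uniform(20, 40, 30), index=idx)
        col = pd.Series(rng.normal(0, 1, 30), index=idx)
        col.iloc[5:12] = np.nan
        recs = associate_scores(dmbmi, pd.DataFrame({"x": col}))
        oracle = len(set(dmbmi.index) & set(col.dropna().index))
        assert recs[0].extra["n_overlap"] == oracle

    def test_bounds_on_records(self):
        rng = np.random.default_rng(5)
        idx = [f"S{i}" for i in range(50)]
        dmbmi = pd.Series(rng.uniform(20, 40, 50), index=idx)
        scores = pd.DataFrame(rng.normal(0, 1, (50, 4)), index=idx,
                              columns=list("abcd"))
        for rec in associate_scores(dmbmi, scores):
            assert abs(rec.r) <= 1
            assert 0 < rec.p_value <= 1

    def test_insufficient_overlap_rejected(self):
        dmbmi = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        scores = pd.DataFrame({"x": [1.0]}, index=["a"])
        with pytest.raises(AlignmentError):
            associate_scores(dmbmi, scores)


class TestBuildScoreTable:
    def test_merged_table(self, small_cohort):
        cohort, _ = small_cohort
        external = pd.DataFrame({
            "sample_id": cohort.beta.sample_ids,
            "TIDE": np.random.default_rng(0).normal(0, 1,
                                                    cohort.beta.n_samples),
        })
        table, meta = build_score_table(expr=cohort.expression,
                                        mutations=cohort.mutation_counts,
                                        external=external)
        assert {"TMB", "IFNG", "APS", "TIDE"} <= set(table.columns)
        assert (table["TMB"] >= 0).all()
        # TMB recomputable: count / 38
        np.testing.assert_allclose(
            table["TMB"].to_numpy(),
            cohort.mutation_counts.to_numpy() / 38.0)
        assert meta["APS"]["aggregation"] == "unweighted mean"
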