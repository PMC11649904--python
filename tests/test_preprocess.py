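import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from modfuse.core_io import FeatureMatrix, ValidationError
from modfuse.preprocess import (
    EXCLUDED,
    annotate_snps_to_genes,
    assign_labels,
    drop_high_missingness,
    hwe_test,
    knn_impute,
    mahalanobis_filter,
    one_hot_encode,
    regress_out_covariates,
    snp_qc,
    zscore_standardize,
)


class TestAssignLabels:
    @pytest.mark.parametrize(
        "baseline,followup,prevalent,incident",
        [
            (3, None, 1, EXCLUDED),      # score at threshold is a case
            (10, None, 1, EXCLUDED),
            (2, 3, 0, 1),                # baseline control crossing at follow-up
            (2, 2, 0, 0),
            (0, None, 0, EXCLUDED),      # missing follow-up excluded
            (None, 5, EXCLUDED, EXCLUDED),
        ],
    )
    def test_mnsi_rule(self, baseline, followup, prevalent, incident):
        assert assign_labels(baseline, followup) == (prevalent, incident)

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValidationError):
            assign_labels(11, None)


class TestHweTest:
    def test_exact_equilibrium(self):
        # (25, 50, 25) are the exact HWE proportions at p=0.5
        assert hwe_test(25, 50, 25) == pytest.approx(1.0)

    def test_no_heterozygotes_extreme(self):
        # expected (25,50,25); chi2 = 25+50+25 = 100
        p = hwe_test(50, 0, 50)
        assert p < 1e-10

    def test_monomorphic_convention(self):
        assert hwe_test(10, 0, 0) == 1.0
        assert hwe_test(0, 0, 7) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            hwe_test(-1, 0, 1)

    def test_agrees_with_exact_multinomial_oracle(self, rng):
        """Chi-square p tracks an exact multinomial enumeration for n>=100."""
        from scipy.special import gammaln

        def levene_haldane_p(nAA, nAa, naa):
            """Exact test conditioning on the minor-allele count."""
            n = nAA + nAa + naa
            m = 2 * naa + nAa  # alt allele count
            m = min(m, 2 * n - m)
            hs = np.arange(m % 2, m + 1, 2)
            logp = (
                hs * np.log(2)
                + gammaln(n + 1)
                - gammaln((m - hs) / 2 + 1)
                - gammaln(hs + 1)
                - gammaln((2 * n - m - hs) / 2 + 1)
                + gammaln(m + 1)
                + gammaln(2 * n - m + 1)
                - gammaln(2 * n + 1)
            )
            p = np.exp(logp - logp.max())
            p /= p.sum()
            obs = p[hs == nAa][0]
            return p[p <= obs + 1e-12].sum()

        chis, exacts = [], []
        for _ in range(50):
            n = int(rng.integers(100, 300))
            q = float(rng.uniform(0.15, 0.5))
            geno = rng.choice(3, size=n, p=[(1 - q) ** 2,
                                            2 * q * (1 - q), q**2])
            nAA, nAa, naa = np.bincount(geno, minlength=3)
            chis.append(hwe_test(nAA, nAa, naa))
            exacts.append(levene_haldane_p(nAA, nAa, naa))
        diffs = np.abs(np.array(chis) - np.array(exacts))
        # the exact test is discrete and conservative; the continuous
        # chi-square tracks it closely in rank and typically in value
        assert np.median(diffs) < 0.08
        assert diffs.max() < 0.4
        assert sps.spearmanr(chis, exacts).statistic > 0.95


class TestSnpQc:
    def _matrix(self, values):
        values = np.asarray(values, dtype=float)
        return FeatureMatrix(
            "genomic",
            pd.DataFrame(
                values,
                index=[f"S{i}" for i in range(values.shape[0])],
                columns=[f"snp{j}" for j in range(values.shape[1])],
            ),
        )

    def test_missing_rate_threshold_is_inclusive(self, rng):
        X = rng.binomial(2, 0.3, size=(100, 2)).astype(float)
        X[:2, 0] = np.nan  # 2% missing >= 1% threshold
        out, report = snp_qc(self._matrix(X))
        assert "snp0" not in out.feature_ids
        reasons = report.removed.set_index("item")["reason"]
        assert reasons.loc["snp0"] == "missing_rate"

    def test_rare_allele_removed(self):
        X = np.zeros((100, 2))
        X[0, 0] = 1.0  # MAF = 1/200 = 0.005 < 0.01
        X[:, 1] = np.tile([0, 1, 2, 1], 25)
        out, report = snp_qc(self._matrix(X))
        assert "snp0" not in out.feature_ids
        assert report.removed.set_index("item").loc["snp0", "reason"] == "maf"

    def test_clean_matrix_unchanged(self, rng):
        X = rng.binomial(2, 0.4, size=(200, 5)).astype(float)
        fm = self._matrix(X)
        out, report = snp_qc(fm)
        assert report.removed.empty
        pd.testing.assert_frame_equal(out.data, fm.data)

    def test_non_dosage_value_rejected(self):
        X = np.zeros((4, 1))
        X[1, 0] = 3.0
        with pytest.raises(ValidationError, match="snp0"):
            snp_qc(self._matrix(X))

    def test_heterozygosity_outlier_sample_removed(self, rng):
        X = rng.binomial(2, 0.4, size=(200, 50)).astype(float)
        X[0, :] = 1.0  # fully heterozygous sample
        out, report = snp_qc(self._matrix(X))
        removed = report.removed
        assert ("S0" == removed.loc[removed["kind"] == "sample", "item"]).any()
        assert "S0" not in out.sample_ids

    def test_each_removal_reported_once(self, rng):
        X = rng.binomial(2, 0.3, size=(100, 3)).astype(float)
        X[:5, 0] = np.nan
        _, report = snp_qc(self._matrix(X))
        assert not report.removed["item"].duplicated().any()


class TestSnpGeneAnnotation:
    GENES = pd.DataFrame(
        {
            "chrom": ["1", "1"],
            "start": [10_000, 50_000],
            "end": [12_000, 55_000],
            "id": ["GENE_A", "GENE_B"],
            "strand": ["+", "-"],
        }
    )

    def _map(self, pos, chrom="1"):
        snps = pd.DataFrame({"chrom": [chrom], "pos": [pos], "id": ["rs1"]})
        return annotate_snps_to_genes(snps, self.GENES, 2000, 500)

    def test_upstream_window_inclusive(self):
        assert self._map(10_000 - 1000).mapping["rs1"] == ("GENE_A",)

    def test_beyond_downstream_window_unmapped(self):
        assert "rs1" not in self._map(12_000 + 501).mapping

    def test_inside_gene_body_mapped(self):
        assert self._map(11_000).mapping["rs1"] == ("GENE_A",)

    def test_minus_strand_window_mirrored(self):
        # upstream of a - strand gene lies beyond its end coordinate
        assert self._map(55_000 + 1500).mapping["rs1"] == ("GENE_B",)
        assert "rs1" not in self._map(50_000 - 1500).mapping

    def test_unknown_chromosome_unmapped(self):
        assert "rs1" not in self._map(11_000, chrom="7").mapping


class TestKnnImpute:
    def test_duplicate_row_donates_value(self):
        df = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, np.nan], [9.0, 9.0, 9.0]],
            index=["S1", "S2", "S3"],
            columns=["a", "b", "c"],
        )
        out = knn_impute(FeatureMatrix("metabolomic", df), k=1)
        assert out.data.loc["S2", "c"] == pytest.approx(3.0)

    def test_complete_matrix_identity(self, rng):
        df = pd.DataFrame(rng.standard_normal((6, 4)),
                          index=[f"S{i}" for i in range(6)],
                          columns=list("abcd"))
        fm = FeatureMatrix("metabolomic", df)
        pd.testing.assert_frame_equal(knn_impute(fm, k=2).data, df)

    def test_observed_cells_never_altered(self, rng):
        X = rng.standard_normal((20, 6))
        mask = rng.random((20, 6)) < 0.15
        Xm = np.where(mask, np.nan, X)
        fm = FeatureMatrix("metabolomic", pd.DataFrame(
            Xm, index=[f"S{i}" for i in range(20)], columns=list("abcdef")))
        out = knn_impute(fm, k=3).data.to_numpy()
        assert np.allclose(out[~mask], X[~mask])
        assert not np.isnan(out).any()

    def test_matches_brute_force_neighbour_oracle(self, rng):
        X = rng.standard_normal((5, 3))
        X[2, 1] = np.nan
        ids = [f"S{i}" for i in range(5)]
        fm = FeatureMatrix("metabolomic", pd.DataFrame(
            X, index=ids, columns=list("abc")))
        out = knn_impute(fm, k=2)
        # oracle: exhaustive pairwise mean-squared distance on shared columns
        dists = []
        for i in range(5):
            if i == 2:
                continue
            shared = [j for j in range(3) if j != 1]
            d = np.mean((X[2, shared] - X[i, shared]) ** 2)
            dists.append((d, i))
        nearest = [i for _, i in sorted(dists)[:2]]
        assert out.data.loc["S2", "b"] == pytest.approx(
            np.mean([X[i, 1] for i in nearest]))

    def test_fully_missing_feature_rejected(self):
        df = pd.DataFrame([[1.0, np.nan], [2.0, np.nan]],
                          index=["S1", "S2"], columns=["a", "b"])
        with pytest.raises(ValidationError, match="missing in all"):
            knn_impute(FeatureMatrix("metabolomic", df), k=1)


class TestMissingnessFilter:
    def test_strictly_greater_dropped(self):
        X = np.ones((100, 2))
        X[:71, 0] = np.nan  # 71% missing
        X[:70, 1] = np.nan  # exactly 70% kept
        fm = FeatureMatrix("metabolomic", pd.DataFrame(
            X, index=[f"S{i}" for i in range(100)], columns=["drop", "keep"]))
        out = drop_high_missingness(fm, 0.70)
        assert out.feature_ids == ["keep"]

    def test_fully_observed_unchanged(self, rng):
        df = pd.DataFrame(rng.standard_normal((10, 3)),
                          index=[f"S{i}" for i in range(10)],
                          columns=list("abc"))
        fm = FeatureMatrix("metabolomic", df)
        pd.testing.assert_frame_equal(
            drop_high_missingness(fm, 0.1).data, df)


class TestMahalanobisFilter:
    def test_gross_outlier_removed(self, rng):
        X = rng.standard_normal((200, 5))
        X[0, 0] = 10.0 * X[:, 0].std() * np.sqrt(5)
        fm = FeatureMatrix("metabolomic", pd.DataFrame(
            X, index=[f"S{i}" for i in range(200)], columns=list("abcde")))
        out, removed = mahalanobis_filter(fm, cutoff=4.0)
        assert "S0" in removed

    def test_homogeneous_data_mostly_kept(self, rng):
        # standardised distances concentrate near 1 << 4
        X = rng.standard_normal((200, 5))
        fm = FeatureMatrix("metabolomic", pd.DataFrame(
            X, index=[f"S{i}" for i in range(200)], columns=list("abcde")))
        _, removed = mahalanobis_filter(fm, cutoff=4.0)
        assert len(removed) <= 10

    def test_duplicate_central_sample_retained(self, rng):
        X = rng.standard_normal((50, 4))
        X[1] = X[0] = 0.0
        fm = FeatureMatrix("metabolomic", pd.DataFrame(
            X, index=[f"S{i}" for i in range(50)], columns=list("abcd")))
        _, removed = mahalanobis_filter(fm, cutoff=4.0)
        assert "S0" not in removed and "S1" not in removed


class TestZscore:
    def test_three_point_column(self):
        fm = FeatureMatrix("transcriptomic", pd.DataFrame(
            {"g": [1.0, 2.0, 3.0]}, index=["a", "b", "c"]))
        out = zscore_standardize(fm)
        assert np.allclose(out.data["g"], [-1.0, 0.0, 1.0])

    def test_idempotent_on_complete_data(self, rng):
        fm = FeatureMatrix("transcriptomic", pd.DataFrame(
            rng.standard_normal((30, 4)) * 5 + 2,
            index=[f"S{i}" for i in range(30)], columns=list("abcd")))
        once = zscore_standardize(fm)
        twice = zscore_standardize(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_missing_preserved_two_point(self):
        fm = FeatureMatrix("metabolomic", pd.DataFrame(
            {"g": [1.0, np.nan, 3.0]}, index=["a", "b", "c"]))
        out = zscore_standardize(fm)
        expected = (np.array([1.0, 3.0]) - 2.0) / np.sqrt(2.0)
        assert np.isnan(out.data.loc["b", "g"])
        assert np.allclose(out.data.loc[["a", "c"], "g"], expected)

    def test_constant_feature_dropped(self):
        fm = FeatureMatrix("clinical", pd.DataFrame(
            {"c": [1.0, 1.0], "v": [0.0, 1.0]}, index=["a", "b"]))
        out = zscore_standardize(fm)
        assert out.feature_ids == ["v"]


class TestOneHot:
    def test_three_level_column_rows_sum_to_one(self):
        df = pd.DataFrame({"smoker": ["never", "ex", "current", "never"]})
        out = one_hot_encode(df)
        assert out.shape[1] == 3
        assert np.allclose(out.data.sum(axis=1), 1.0)

    def test_numeric_passthrough(self):
        df = pd.DataFrame({"age": [50.0, 61.0], "flag": [0, 1]})
        out = one_hot_encode(df)
        assert out.feature_ids == ["age", "flag"]
        assert np.allclose(out.data["flag"], [0.0, 1.0])

    def test_mixed_column_count(self):
        df = pd.DataFrame({
            "sex": ["m", "f", "m"],
            "smoker": ["never", "ex", "current"],
            "age": [50.0, 61.0, 47.0],
        })
        assert one_hot_encode(df).shape[1] == 2 + 3 + 1

    def test_single_level_dropped(self):
        df = pd.DataFrame({"const": ["x", "x"], "age": [1.0, 2.0]})
        assert one_hot_encode(df).feature_ids == ["age"]


class TestRegressOut:
    def _fm(self, X, ids):
        return FeatureMatrix("transcriptomic", pd.DataFrame(
            X, index=ids, columns=[f"g{j}" for j in range(X.shape[1])]))

    def test_identical_covariate_zeroes_feature(self, rng):
        x = rng.standard_normal(30)
        ids = [f"S{i}" for i in range(30)]
        fm = self._fm(x[:, None], ids)
        cov = pd.DataFrame({"c": x}, index=ids)
        out = regress_out_covariates(fm, cov)
        assert np.allclose(out.data["g0"], 0.0, atol=1e-10)

    def test_orthogonal_covariate_only_centers(self, rng):
        n = 1000
        ids = [f"S{i}" for i in range(n)]
        x = rng.standard_normal(n)
        c = rng.standard_normal(n)
        c -= c.mean()
        xc = x - x.mean()
        c -= c @ xc / (xc @ xc) * xc  # orthogonal to the centred feature
        out = regress_out_covariates(
            self._fm(x[:, None], ids), pd.DataFrame({"c": c}, index=ids))
        assert np.allclose(out.data["g0"], x - x.mean(), atol=1e-10)

    def test_known_coefficient_recovery(self, rng):
        n = 500
        ids = [f"S{i}" for i in range(n)]
        c = rng.standard_normal(n)
        noise = rng.standard_normal(n)
        feature = 2.0 * c + noise
        out = regress_out_covariates(
            self._fm(feature[:, None], ids), pd.DataFrame({"c": c}, index=ids))
        resid_var = out.data["g0"].var()
        assert abs(resid_var - noise.var()) / noise.var() < 0.10

    def test_collinear_covariates_rejected(self, rng):
        n = 20
        ids = [f"S{i}" for i in range(n)]
        c = rng.standard_normal(n)
        cov = pd.DataFrame({"c1": c, "c2": 2 * c}, index=ids)
        with pytest.raises(ValidationError, match="c2"):
            regress_out_covariates(
                self._fm(rng.standard_normal((n, 1)), ids), cov)
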