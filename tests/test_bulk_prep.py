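"""Bulk normalization, filtering, covariate encoding and QC diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from braincyto import bulk_prep
from braincyto.bulk_prep import (
    FilterParams,
    correlation_cluster_qc,
    cpm,
    encode_covariates,
    filter_genes_bulk,
    marker_checks,
    pca_qc,
    quantile_normalize,
    suggest_batch_split,
)


class TestCPM:
    def test_single_expressed_gene_takes_the_million(self):
        counts = np.array([[30, 7], [0, 0]])
        out = cpm(counts)
        np.testing.assert_allclose(out[0], [1e6, 1e6])

    def test_doubling_a_sample_leaves_cpm_unchanged(self):
        counts = np.array([[5, 10], [15, 20]])
        np.testing.assert_allclose(cpm(counts)[:, 0], cpm(counts * 2)[:, 0])

    def test_worked_arithmetic(self):
        counts = np.array([[5], [15]])
        np.testing.assert_allclose(cpm(counts)[:, 0], [250000, 750000])

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            cpm(np.array([[0], [0]]))


class TestGeneFilter:
    def test_threshold_formula(self):
        assert FilterParams(L=20, N=3).cpm_threshold == pytest.approx(0.5)

    def test_boundary_counts_of_passing_samples(self):
        params = FilterParams(L=20, N=3)
        mat = np.array(
            [
                [1.0, 1.0, 0.1, 0.1],  # above threshold in N-1 samples only
                [1.0, 1.0, 1.0, 0.1],  # in exactly N samples
            ]
        )
        kept = filter_genes_bulk(mat, params)
        assert 0 not in kept and 1 in kept

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FilterParams(L=0, N=1)
        with pytest.raises(ValueError):
            FilterParams(L=1, N=0)

    def test_sample_order_irrelevant(self):
        rng = np.random.default_rng(0)
        mat = rng.uniform(0, 2, size=(50, 8))
        params = FilterParams(L=10, N=4)
        a = filter_genes_bulk(mat, params)
        b = filter_genes_bulk(mat[:, ::-1], params)
        np.testing.assert_array_equal(a, b)


class TestQuantileNormalize:
    def test_identical_samples_unchanged(self):
        x = np.array([[1.0, 1.0], [3.0, 3.0], [2.0, 2.0]])
        out = quantile_normalize(x).data.to_numpy()
        np.testing.assert_allclose(out, x)

    def test_three_by_three_hand_computed(self):
        # ranks per column -> replace by cross-sample means of sorted values.
        # sorted columns: (1,4,6),(2,3,8),(0,5,7) -> reference (1,4,7)
        x = np.array(
            [
                [4.0, 3.0, 5.0],
                [1.0, 8.0, 0.0],
                [6.0, 2.0, 7.0],
            ]
        )
        expected = np.array(
            [
                [4.0, 4.0, 4.0],
                [1.0, 7.0, 1.0],
                [7.0, 1.0, 7.0],
            ]
        )
        out = quantile_normalize(x).data.to_numpy()
        np.testing.assert_allclose(out, expected)

    def test_all_quantile_vectors_equal_after_normalization(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(40, 6))
        out = quantile_normalize(x).data.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 6):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        arrays(
            dtype=float,
            shape=st.tuples(st.integers(5, 25), st.integers(2, 6)),
            elements=st.floats(-50, 50, allow_nan=False),
            unique=True,
        )
    )
    def test_idempotent_on_tie_free_columns(self, x):
        # exact idempotence holds when each column is tie-free (ties shift
        # the pooled reference slightly on re-normalization)
        once = quantile_normalize(x).data.to_numpy()
        twice = quantile_normalize(once).data.to_numpy()
        np.testing.assert_allclose(once, twice, atol=1e-10)

    def test_ties_get_the_average_of_tied_rank_values(self):
        # column 0 tie at ranks 2-3: both get the mean of reference[1:3]
        x = np.array([[0.0, 10.0], [5.0, 20.0], [5.0, 30.0], [9.0, 40.0]])
        out = quantile_normalize(x).data.to_numpy()
        ref = np.sort(x, axis=0).mean(axis=1)
        assert out[1, 0] == out[2, 0] == pytest.approx((ref[1] + ref[2]) / 2)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            quantile_normalize(np.ones((5, 1)))


class TestEncodeCovariates:
    def _meta(self):
        return pd.DataFrame(
            {
                "disease": [0, 0, 1, 1, 1],
                "age": [70.0, 75, 80, 85, 72],
                "sex": [0, 1, 1, 0, 1],
                "rin": [8.5, 9.0, 7.9, 8.6, 9.4],
                "batch": [0, 1, 0, 1, 0],
                "degradation_slope": [4.0, 5.0, 5.5, 6.0, 3.0],
                "neuronal_fraction": [0.7, 0.65, 0.5, 0.62, 0.58],
            },
            index=[f"s{i}" for i in range(5)],
        )

    def test_rin_at_cut_is_low(self):
        cov = encode_covariates(self._meta(), "ad_rnaseq", rin_cut=8.5)
        assert cov.loc["s0", "rin_group"] == 0.0  # 8.5 at the 8.5 cut: low
        assert cov.loc["s1", "rin_group"] == 1.0

    def test_degradation_at_cut_is_low(self):
        cov = encode_covariates(self._meta(), "pd_microarray")
        assert cov.loc["s1", "degradation_group"] == 0.0  # slope 5 at cut 5
        assert cov.loc["s2", "degradation_group"] == 1.0

    def test_centered_columns_have_zero_mean(self):
        cov = encode_covariates(self._meta(), "ad_rnaseq")
        assert abs(cov["disease_c"].mean()) < 1e-12
        assert abs(cov["neuronal_c"].mean()) < 1e-12

    def test_interaction_is_product_of_centered_parents(self):
        cov = encode_covariates(self._meta(), "ad_rnaseq")
        np.testing.assert_allclose(
            cov["interaction"], cov["disease_c"] * cov["neuronal_c"]
        )

    def test_interaction_only_for_ad_profile(self):
        assert "interaction" not in encode_covariates(self._meta(), "pd_rnaseq")

    def test_missing_field_named_in_error(self):
        meta = self._meta().drop(columns=["rin"])
        with pytest.raises(ValueError, match="rin"):
            encode_covariates(meta, "ad_rnaseq")


class TestPCAQC:
    def _planted(self, n=40, genes=300, seed=2):
        """Single dominant composition factor driving half the genes."""
        rng = np.random.default_rng(seed)
        f = rng.uniform(0.4, 0.9, size=n)
        loadings = np.zeros(genes)
        loadings[: genes // 2] = rng.normal(2.0, 0.3, size=genes // 2)
        X = np.outer(loadings, f - f.mean()) + rng.normal(0, 0.1, size=(genes, n))
        meta = pd.DataFrame(
            {"disease": rng.integers(0, 2, n), "age": rng.normal(75, 5, n),
             "neuronal_fraction": f},
            index=[f"s{i}" for i in range(n)],
        )
        norm = bulk_prep.NormalizedMatrix(
            data=pd.DataFrame(X, columns=meta.index), library_sizes=None
        )
        return norm, meta

    def test_dominant_composition_axis_found_on_pc1(self):
        norm, meta = self._planted()
        rep = pca_qc(norm, meta)
        assert abs(rep.correlations.loc["PC1", "neuronal_fraction"]) >= 0.9

    def test_variance_explained_sums_to_hundred(self):
        norm, meta = self._planted()
        rep = pca_qc(norm, meta)
        assert rep.variance_explained.sum() == pytest.approx(100.0, abs=1e-8)

    def test_duplicated_samples_have_identical_scores(self):
        norm, meta = self._planted(n=10)
        dup = bulk_prep.NormalizedMatrix(
            data=pd.concat(
                [norm.data, norm.data.add_suffix("_dup")], axis=1
            ),
            library_sizes=None,
        )
        meta2 = pd.concat([meta, meta.set_index(meta.index + "_dup")])
        rep = pca_qc(dup, meta2)
        a = rep.scores.iloc[:10].to_numpy()
        b = rep.scores.iloc[10:].to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-8)


class TestClusterQC:
    def test_pure_noise_sample_flagged(self):
        rng = np.random.default_rng(3)
        shared = rng.normal(size=200)
        X = shared[:, None] + rng.normal(0, 0.2, size=(200, 12))
        X[:, 0] = rng.normal(size=200)  # one independent sample
        norm = bulk_prep.NormalizedMatrix(
            data=pd.DataFrame(X, columns=[f"s{i}" for i in range(12)]),
            library_sizes=None,
        )
        _, flags = correlation_cluster_qc(norm)
        assert "s0" in flags

    def test_identical_samples_merge_first(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 5))
        X[:, 1] = X[:, 0]
        norm = bulk_prep.NormalizedMatrix(
            data=pd.DataFrame(X, columns=[f"s{i}" for i in range(5)]),
            library_sizes=None,
        )
        Z, _ = correlation_cluster_qc(norm)
        assert set(Z[0, :2].astype(int)) == {0, 1}
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-8)

    def test_homogeneous_cohort_unflagged(self):
        rng = np.random.default_rng(5)
        shared = rng.normal(size=300)
        X = shared[:, None] + rng.normal(0, 0.15, size=(300, 15))
        norm = bulk_prep.NormalizedMatrix(
            data=pd.DataFrame(X, columns=[f"s{i}" for i in range(15)]),
            library_sizes=None,
        )
        _, flags = correlation_cluster_qc(norm)
        assert flags == []


class TestMarkerChecks:
    def _cohort(self, effect, n=30, seed=6):
        rng = np.random.default_rng(seed)
        disease = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        genes = [f"g{i}" for i in range(50)]
        X = rng.normal(size=(50, n))
        X[:5] -= effect * disease  # neuronal markers drop in disease
        norm = bulk_prep.NormalizedMatrix(
            data=pd.DataFrame(X, index=genes, columns=[f"s{i}" for i in range(n)]),
            library_sizes=None,
        )
        meta = pd.DataFrame({"disease": disease}, index=norm.data.columns)
        return norm, meta

    def test_planted_neuronal_loss_detected(self):
        norm, meta = self._cohort(effect=2.0)
        table = marker_checks(norm, meta, {"neuron": [f"g{i}" for i in range(5)]})
        assert (table["fdr"] < 0.05).all()
        assert (table["mean_diff"] < 0).all()

    def test_null_cohort_rarely_significant(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(1000, 40))
        norm = bulk_prep.NormalizedMatrix(
            data=pd.DataFrame(
                X, index=[f"g{i}" for i in range(1000)],
                columns=[f"s{i}" for i in range(40)],
            ),
            library_sizes=None,
        )
        meta = pd.DataFrame(
            {"disease": np.r_[np.zeros(20), np.ones(20)]}, index=norm.data.columns
        )
        table = marker_checks(
            norm, meta, {"all": [f"g{i}" for i in range(1000)]}
        )
        assert (table["p"] < 0.05).mean() <= 0.07

    def test_missing_and_degenerate_markers_reported(self):
        norm, meta = self._cohort(effect=0.0)
        norm.data.loc["g9"] = 1.0  # zero variance in both arms
        table = marker_checks(norm, meta, {"x": ["g9", "absent_gene"]})
        by_gene = table.set_index("gene")
        assert by_gene.loc["absent_gene", "status"] == "missing"
        assert by_gene.loc["g9", "status"] == "na"
        assert np.isnan(by_gene.loc["g9", "t"])


def test_batch_split_suggestion_recovers_planted_batches():
    rng = np.random.default_rng(8)
    batch = np.r_[np.zeros(10), np.ones(10)]
    X = rng.normal(size=(200, 20)) + 3.0 * np.outer(rng.normal(size=200), batch)
    norm = bulk_prep.NormalizedMatrix(
        data=pd.DataFrame(X, columns=[f"s{i}" for i in range(20)]),
        library_sizes=None,
    )
    suggestion = suggest_batch_split(norm).to_numpy()
    agreement = max((suggestion == batch).mean(), (suggestion != batch).mean())
    assert agreement == 1.0
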