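"""Quantile normalization, surrogate variables and study-wise median centering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from emtint.io import EPITHELIAL, MESENCHYMAL
from emtint.normalization import (
    METHODS,
    estimate_surrogate_variables,
    median_center_standardize,
    normalize,
    quantile_normalize,
    regress_out_svs,
)
from emtint.simulate import SyntheticConfig, generate_multistudy

PHENO_10 = [EPITHELIAL, MESENCHYMAL] * 5


class TestQuantileNormalize:
    def test_two_column_hand_example(self):
        out = quantile_normalize(np.array([[1.0, 4.0], [3.0, 2.0]]))
        np.testing.assert_allclose(out, [[1.5, 3.5], [3.5, 1.5]])

    def test_constant_matrix_unchanged(self):
        const = np.full((5, 3), 2.0)
        np.testing.assert_allclose(quantile_normalize(const), const)

    def test_ties_get_mean_of_occupied_ranks(self):
        # column 2 is constant: all its entries occupy ranks 1..3 -> mean of reference
        out = quantile_normalize(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))
        np.testing.assert_allclose(out[:, 1], np.full(3, out[:, 0].mean()))

    @settings(max_examples=25, deadline=None)
    @given(hnp.arrays(np.float64, st.tuples(st.integers(2, 12), st.integers(1, 5)),
                      elements=st.floats(-50, 50, allow_nan=False,
                                         allow_subnormal=False),
                      unique=True))
    def test_idempotent_on_tie_free_data(self, arr):
        once = quantile_normalize(arr)
        np.testing.assert_allclose(quantile_normalize(once), once, atol=1e-12)

    def test_tie_free_columns_share_distribution_exactly(self):
        rng = np.random.default_rng(14)
        arr = rng.normal(size=(30, 5))
        out = quantile_normalize(arr)
        ref = np.sort(out[:, 0])
        for j in range(5):
            np.testing.assert_array_equal(np.sort(out[:, j]), ref)

    def test_rank_order_preserved_within_column(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(size=(40, 4))
        out = quantile_normalize(arr)
        for j in range(4):
            assert (np.argsort(arr[:, j]) == np.argsort(out[:, j])).all()


class TestSurrogateVariables:
    def test_pure_phenotype_signal_gives_zero_svs(self):
        p = np.array([1.0 if v == EPITHELIAL else 0.0 for v in PHENO_10])
        values = np.outer(np.arange(1, 6.0), p) + 3.0  # exact fit, zero residual
        svs = estimate_surrogate_variables(values, PHENO_10, k="auto", random_state=0)
        assert svs.k == 0

    def test_requested_k_gives_orthonormal_columns(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(100, 10))
        svs = estimate_surrogate_variables(values, PHENO_10, k=2, random_state=0)
        assert svs.sv_matrix.shape == (10, 2)
        np.testing.assert_allclose(svs.sv_matrix.T @ svs.sv_matrix, np.eye(2), atol=1e-10)
        assert (np.diff(svs.singular_values) <= 1e-9).all()

    def test_k_too_large_rejected(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match="k="):
            estimate_surrogate_variables(rng.normal(size=(50, 10)), PHENO_10, k=8)

    def test_single_batch_vector_recovered(self):
        """One planted batch direction appears as SV1 with |r| >= 0.9."""
        rng = np.random.default_rng(7)
        n_genes, n = 2000, 40
        pheno = np.tile([EPITHELIAL, MESENCHYMAL], n // 2)
        p = (pheno == EPITHELIAL).astype(float)
        batch = np.tile([1.0, 1.0, 0.0, 0.0], n // 4)  # balanced across phenotypes
        delta = np.zeros(n_genes)
        de = rng.choice(n_genes, 200, replace=False)
        delta[de] = rng.normal(1.0, 0.2, 200) * rng.choice([-1.0, 1.0], 200)
        values = (
            rng.normal(7, 2, n_genes)[:, None]
            + delta[:, None] * p
            + rng.normal(0, 2.0, n_genes)[:, None] * batch
            + rng.normal(0, 1.0, (n_genes, n))
        )
        svs = estimate_surrogate_variables(values, pheno, k="auto", random_state=0)
        assert svs.k >= 1
        assert abs(np.corrcoef(svs.sv_matrix[:, 0], batch)[0, 1]) >= 0.9

        corrected = regress_out_svs(values, pheno, svs)
        centered = corrected - corrected.mean(axis=1, keepdims=True)
        bc = batch - batch.mean()
        gene_corr = centered @ bc / (
            np.linalg.norm(centered, axis=1) * np.linalg.norm(bc)
        )
        assert np.median(np.abs(gene_corr)) < 0.1
        before = values[de][:, p == 1].mean(1) - values[de][:, p == 0].mean(1)
        after = corrected[de][:, p == 1].mean(1) - corrected[de][:, p == 0].mean(1)
        assert (np.abs(after - before) / np.abs(before)).max() < 0.1

    def test_known_covariate_absorbs_batch_structure(self):
        """A batch supplied as a known covariate leaves no hidden factor to find."""
        rng = np.random.default_rng(5)
        n_genes, n = 500, 20
        pheno = np.tile([EPITHELIAL, MESENCHYMAL], n // 2)
        batch = np.tile([1.0, 1.0, 0.0, 0.0], n // 4)
        values = (
            rng.normal(0, 2, n_genes)[:, None] * batch
            + rng.normal(0, 1, (n_genes, n))
        )
        blind = estimate_surrogate_variables(values, pheno, k="auto", random_state=0)
        informed = estimate_surrogate_variables(
            values, pheno, k="auto", random_state=0, covariates=batch
        )
        assert blind.k >= 1
        assert informed.k == 0

    def test_collinear_covariate_rejected(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=(50, 10))
        p = np.array([1.0 if v == EPITHELIAL else 0.0 for v in PHENO_10])
        with pytest.raises(ValueError, match="collinear"):
            estimate_surrogate_variables(values, PHENO_10, covariates=2 * p - 1)

    def test_auto_k_zero_on_pure_noise_at_nominal_rate(self):
        """Structure-free residuals keep k=0 at ~ the nominal 5% test level."""
        nonzero = 0
        for seed in range(60):
            noise = np.random.default_rng(seed).normal(size=(300, 20))
            svs = estimate_surrogate_variables(
                noise, np.tile([EPITHELIAL, MESENCHYMAL], 10), k="auto", random_state=seed
            )
            nonzero += svs.k > 0
        assert nonzero <= 8  # binomial(60, 0.05) upper tail


class TestRegressOutSvs:
    def test_k_zero_is_identity(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(30, 10))
        svs = estimate_surrogate_variables(
            np.zeros((30, 10)) + np.outer(np.arange(30.0),
                                          [1.0 if v == EPITHELIAL else 0.0 for v in PHENO_10]),
            PHENO_10, k=0,
        )
        np.testing.assert_allclose(regress_out_svs(values, PHENO_10, svs), values)

    def test_exact_linear_removal(self):
        """Data = phenotype effect + c * SV exactly -> SV part removed, signal kept."""
        rng = np.random.default_rng(3)
        n = 10
        p = np.array([1.0 if v == EPITHELIAL else 0.0 for v in PHENO_10])
        design = np.column_stack([np.ones(n), p])
        q, _ = np.linalg.qr(design)
        sv = rng.normal(size=n)
        sv -= q @ (q.T @ sv)  # orthogonalize against [1, phenotype] for exactness
        sv /= np.linalg.norm(sv)
        effect = np.outer(np.arange(5.0), p)
        loadings = rng.normal(size=5)
        values = effect + np.outer(loadings, sv) + 1.0
        svs = estimate_surrogate_variables(values, PHENO_10, k=1, random_state=0)
        out = regress_out_svs(values, PHENO_10, svs)
        np.testing.assert_allclose(out, effect + 1.0, atol=1e-8)


class TestMedianCenterStandardize:
    def test_row_medians_zero_and_column_sd_one(self):
        rng = np.random.default_rng(4)
        values = rng.normal(2, 3, size=(21, 6))
        out = median_center_standardize(values)
        np.testing.assert_allclose(np.median(out, axis=1), 0.0, atol=1e-12)
        # column SDs were 1 before the (row-)centering step
        before = (values - values.mean(0)) / values.std(0, ddof=1)
        np.testing.assert_allclose(before.std(0, ddof=1), 1.0, atol=1e-12)

    def test_symmetric_hand_example(self):
        out = median_center_standardize(np.array([[0.0, 2.0], [2.0, 0.0]]))
        inv_sqrt2 = 1 / np.sqrt(2)
        np.testing.assert_allclose(
            out, [[-inv_sqrt2, inv_sqrt2], [inv_sqrt2, -inv_sqrt2]], atol=1e-12
        )

    def test_per_study_independence(self):
        rng = np.random.default_rng(6)
        block = rng.normal(size=(15, 4))
        single = median_center_standardize(block)
        meta_free = np.hstack([block, block])
        # identical studies processed independently give identical blocks
        from emtint.normalization import StudywiseMedianCenterScaler

        out = StudywiseMedianCenterScaler().fit_transform(
            meta_free.T, studies=np.repeat(["a", "b"], 4)
        ).T
        np.testing.assert_allclose(out[:, :4], single)
        np.testing.assert_allclose(out[:, 4:], single)

    def test_zero_variance_column_rejected(self):
        values = np.array([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        with pytest.raises(ValueError, match="zero-variance"):
            median_center_standardize(values)


class TestNormalizeDispatch:
    def test_unknown_method_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="unknown method"):
            normalize(small_dataset.studies, "XYZ", metadata=small_dataset.metadata)

    def test_none_is_passthrough_and_qn_sva_composes(self, small_dataset):
        from emtint.io import intersect_and_merge
        from emtint.normalization import quantile_normalize as qn

        integrated = intersect_and_merge(small_dataset.studies, small_dataset.metadata)
        none = normalize(integrated, "NONE")
        pd.testing.assert_frame_equal(none.values, integrated.values)

        qn_sva = normalize(integrated, "QN_SVA", random_state=3)
        qned = qn(integrated.values)
        svs = estimate_surrogate_variables(qned, integrated.phenotype, random_state=3)
        manual = regress_out_svs(qned, integrated.phenotype, svs)
        pd.testing.assert_frame_equal(qn_sva.values, manual)

    def test_all_methods_finite_and_same_shape(self, reference_run):
        shapes = {m: nm.values.shape for m, nm in reference_run.normalized.items()}
        assert len(set(shapes.values())) == 1
        for nm in reference_run.normalized.values():
            assert np.isfinite(nm.values.to_numpy()).all()
        assert set(reference_run.normalized) == set(METHODS)

    def test_grouping_rescue_ordering(self, reference_run):
        """Latent-factor correction recovers phenotype grouping best."""
        bh = reference_run.bh["bh_index"]
        assert bh["SVA"] > bh["MCtr"]
        assert bh["QN_SVA"] > bh["MCtr"]
        assert bh["QN"] > bh["NONE"]
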