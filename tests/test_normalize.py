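"""Normalization: quantile targets, centering, residualization, PC handling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ctqtl import (
    ExpressionMatrix,
    GenotypeMatrix,
    log2_center,
    pc_correct_skip_genetic,
    quantile_normalize_median,
    remove_covariates,
    sample_qc_pc1,
    simulate_cohort,
)
from conftest import small_config


def expr_from(array, probe_prefix="p", sample_prefix="s"):
    array = np.asarray(array, dtype=float)
    return ExpressionMatrix(
        values=pd.DataFrame(
            array,
            index=[f"{probe_prefix}{i}" for i in range(array.shape[0])],
            columns=[f"{sample_prefix}{j}" for j in range(array.shape[1])],
        )
    )


class TestQuantileNormalizeMedian:
    def test_two_sample_hand_oracle(self):
        # A=[1,3], B=[2,8]: rank-wise medians are [1.5, 5.5]
        out = quantile_normalize_median(expr_from([[1, 2], [3, 8]]))
        assert np.allclose(out.values.to_numpy(), [[1.5, 1.5], [5.5, 5.5]])

    def test_identical_columns_are_a_fixed_point(self):
        x = expr_from(np.tile([[4.0], [1.0], [2.5]], (1, 5)))
        out = quantile_normalize_median(x)
        assert np.allclose(out.values.to_numpy(), x.values.to_numpy())

    def test_columns_share_the_sorted_target(self, rng):
        x = expr_from(rng.normal(size=(40, 7)))
        out = quantile_normalize_median(x).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 7):
            assert np.allclose(np.sort(out[:, j]), ref)

    def test_rank_order_preserved_within_columns(self, rng):
        x = rng.normal(size=(30, 4))
        out = quantile_normalize_median(expr_from(x)).values.to_numpy()
        for j in range(4):
            assert np.array_equal(np.argsort(x[:, j]), np.argsort(out[:, j]))

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_idempotent_on_tie_free_input(self, seed):
        x = np.random.default_rng(seed).normal(size=(25, 5))
        once = quantile_normalize_median(expr_from(x))
        twice = quantile_normalize_median(once)
        assert np.allclose(once.values.to_numpy(), twice.values.to_numpy(), atol=1e-12)

    def test_ties_get_the_average_reference_value(self):
        # reference (rank-wise medians of sorted columns) is [1.5, 2.5, 6.5];
        # the tied pair in column A sits at average rank 1.5 and gets
        # (1.5 + 2.5) / 2 = 2.0
        out = quantile_normalize_median(expr_from([[1, 2], [1, 8], [5, 4]]))
        col0 = out.values.to_numpy()[:, 0]
        assert col0[0] == col0[1] == pytest.approx(2.0)
        assert col0[2] == pytest.approx(6.5)

    def test_missing_values_rejected(self):
        x = expr_from([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="missing"):
            quantile_normalize_median(x)

    def test_transform_log_appended(self, rng):
        out = quantile_normalize_median(expr_from(rng.normal(size=(10, 3))))
        assert out.transform_log == ["quantile_normalize_median"]


class TestLog2Center:
    def test_constant_matrix_becomes_zero(self):
        out = log2_center(expr_from(np.full((3, 4), 4.0)))
        assert np.allclose(out.values.to_numpy(), 0.0)

    def test_multiplicative_2x2_hand_oracle(self):
        # log2([[1,2],[4,8]]) = [[0,1],[2,3]] is additive in rows/columns,
        # so double centering removes all structure
        out = log2_center(expr_from([[1, 2], [4, 8]]))
        assert np.allclose(out.values.to_numpy(), 0.0, atol=1e-12)

    def test_row_and_column_means_vanish(self, rng):
        out = log2_center(expr_from(rng.lognormal(size=(30, 12))))
        vals = out.values.to_numpy()
        assert np.abs(vals.mean(axis=0)).max() < 1e-8
        assert np.abs(vals.mean(axis=1)).max() < 1e-8

    def test_non_positive_value_error_names_probe_and_sample(self):
        x = expr_from([[1.0, 2.0], [3.0, -1.0]])
        with pytest.raises(ValueError, match="'p1'.*'s1'"):
            log2_center(x)


class TestRemoveCovariates:
    def test_probe_equal_to_covariate_residualizes_to_zero(self, rng):
        cov = pd.DataFrame({"c1": rng.normal(size=20)}, index=[f"s{j}" for j in range(20)])
        x = expr_from(cov["c1"].to_numpy()[None, :])
        out = remove_covariates(x, cov)
        assert np.allclose(out.values.to_numpy(), 0.0, atol=1e-10)

    def test_orthogonal_covariates_only_center(self, rng):
        probe = np.concatenate([np.ones(10), -np.ones(10)]) * 2.0
        cov = pd.DataFrame(
            {"c1": np.concatenate([rng.normal(size=10), np.zeros(10)])},
            index=[f"s{j}" for j in range(20)],
        )
        cov["c1"] -= cov["c1"].mean()
        cov.loc[[f"s{j}" for j in range(10)], "c1"] -= cov["c1"][:10].mean()
        # construct exact orthogonality: covariate supported on first half,
        # probe constant on that half after centering
        c = rng.normal(size=20)
        c -= c.mean()
        probe_orth = np.ones(20) * 3 + np.where(np.arange(20) < 10, 1.0, -1.0)
        c_orth = c - (c @ (probe_orth - probe_orth.mean())) / np.sum(
            (probe_orth - probe_orth.mean()) ** 2
        ) * (probe_orth - probe_orth.mean())
        cov = pd.DataFrame({"c1": c_orth}, index=[f"s{j}" for j in range(20)])
        out = remove_covariates(expr_from(probe_orth[None, :]), cov)
        assert np.allclose(
            out.values.to_numpy()[0], probe_orth - probe_orth.mean(), atol=1e-8
        )

    def test_matches_normal_equation_oracle(self, rng):
        n, k = 20, 3
        cov = pd.DataFrame(
            rng.normal(size=(n, k)),
            index=[f"s{j}" for j in range(n)],
            columns=list("abc"),
        )
        y = rng.normal(size=(5, n))
        out = remove_covariates(expr_from(y), cov).values.to_numpy()
        design = np.column_stack([np.ones(n), cov.to_numpy()])
        hat = design @ np.linalg.inv(design.T @ design) @ design.T
        oracle = (y.T - hat @ y.T).T
        assert np.allclose(out, oracle, atol=1e-8)

    def test_residuals_orthogonal_to_covariates(self, rng):
        n = 30
        cov = pd.DataFrame(
            rng.normal(size=(n, 2)), index=[f"s{j}" for j in range(n)], columns=["a", "b"]
        )
        out = remove_covariates(expr_from(rng.normal(size=(8, n))), cov)
        resid = out.values.to_numpy()
        inner = resid @ cov.to_numpy()
        scale = np.linalg.norm(resid, axis=1)[:, None] * np.linalg.norm(cov.to_numpy(), axis=0)
        assert np.abs(inner / scale).max() < 1e-6

    def test_rank_deficient_covariates_rejected(self, rng):
        c = rng.normal(size=20)
        cov = pd.DataFrame({"a": c, "b": 2 * c}, index=[f"s{j}" for j in range(20)])
        with pytest.raises(ValueError, match="collinear"):
            remove_covariates(expr_from(rng.normal(size=(3, 20))), cov)


class TestSampleQcPc1:
    def test_identical_profiles_all_pass_default_threshold(self, rng):
        profile = rng.normal(size=50)
        x = expr_from(np.tile(profile[:, None], (1, 10)))
        kept, removed = sample_qc_pc1(x, threshold=0.9)
        assert removed == []
        assert kept.n_samples == 10

    def test_noise_sample_among_structured_samples_is_removed(self, rng):
        fx = simulate_cohort(small_config(seed=31, samples_per_cohort=[50, 50]), 0)
        vals = (2 ** (fx.expression.values + 8)).copy()
        noise_col = vals.columns[7]
        vals[noise_col] = rng.permutation(vals[noise_col].to_numpy())
        kept, removed = sample_qc_pc1(quantile_normalize_median(ExpressionMatrix(values=vals)), 0.9)
        assert removed == [noise_col]

    def test_threshold_zero_removes_at_most_half_after_orientation(self, rng):
        x = expr_from(rng.normal(size=(40, 21)))
        kept, removed = sample_qc_pc1(x, threshold=0.0)
        assert len(removed) <= 10  # orientation makes the median non-negative

    def test_all_removed_is_an_error(self, rng):
        # near-orthogonal columns: no sample reaches a 0.99 correlation with
        # the PC1 reference profile, so the filter must refuse to empty the set
        x = expr_from(np.eye(5) + rng.normal(scale=1e-6, size=(5, 5)))
        with pytest.raises(ValueError, match="every sample"):
            sample_qc_pc1(x, threshold=0.99)


class TestPcCorrectSkipGenetic:
    def _genotypes(self, dosage_rows, samples):
        values = pd.DataFrame(
            dosage_rows, index=[f"rs{i}" for i in range(len(dosage_rows))], columns=samples
        )
        return GenotypeMatrix(values=values)

    def test_component_matching_a_snp_is_flagged_and_kept(self, rng):
        n = 60
        samples = [f"s{j}" for j in range(n)]
        dosage = rng.integers(0, 3, size=n).astype(float)
        loading = rng.normal(size=40)
        # expression dominated by a component whose score is the dosage
        vals = np.outer(loading, dosage - dosage.mean()) + rng.normal(scale=0.05, size=(40, n))
        x = ExpressionMatrix(
            values=pd.DataFrame(vals, index=[f"p{i}" for i in range(40)], columns=samples)
        )
        corrected, report = pc_correct_skip_genetic(
            x, self._genotypes([dosage], samples), n_components=5, genetic_p_threshold=5e-8
        )
        assert 0 in report.skipped_genetic_indices
        # the genetic component survives correction: dosage still predicts expression
        marker = corrected.values.to_numpy()[np.argmax(np.abs(loading))]
        assert abs(np.corrcoef(marker, dosage)[0, 1]) > 0.5

    def test_removal_reduces_variance_and_orthogonalizes(self, rng):
        n = 50
        samples = [f"s{j}" for j in range(n)]
        vals = rng.normal(size=(30, n))
        x = ExpressionMatrix(
            values=pd.DataFrame(vals, index=[f"p{i}" for i in range(30)], columns=samples)
        )
        geno = self._genotypes([rng.integers(0, 3, size=n).astype(float)], samples)
        corrected, report = pc_correct_skip_genetic(
            x, geno, n_components=5, genetic_p_threshold=1e-300
        )
        assert report.skipped_genetic_indices == []
        assert corrected.values.to_numpy().var() <= vals.var()
        eig = np.linalg.eigh(np.corrcoef(vals.T))
        scores = eig[1][:, ::-1][:, :5]
        inner = corrected.values.to_numpy() @ scores
        assert np.abs(inner).max() < 1e-8

    def test_n_components_at_rank_rejected(self, rng):
        x = expr_from(rng.normal(size=(10, 8)))
        geno = self._genotypes([np.arange(8, dtype=float) % 3], x.sample_ids)
        with pytest.raises(ValueError, match="n_components"):
            pc_correct_skip_genetic(x, geno, n_components=8)

    def test_sample_permutation_equivariance(self, rng):
        fx = simulate_cohort(small_config(seed=41, samples_per_cohort=[60, 60]), 0)
        x = ExpressionMatrix(values=fx.expression.values)
        corrected, _ = pc_correct_skip_genetic(x, fx.genotypes, n_components=5)
        perm = rng.permutation(x.n_samples)
        cols = [x.sample_ids[i] for i in perm]
        xp = x.subset_samples(cols)
        corrected_p, _ = pc_correct_skip_genetic(xp, fx.genotypes, n_components=5)
        assert np.allclose(
            corrected_p.values.to_numpy(),
            corrected.values.loc[:, cols].to_numpy(),
            atol=1e-8,
        )

    def test_marker_fraction_correlation_attenuated_by_correction(self):
        # the strongest expression components carry the cell-composition signal,
        # so removing them should strip most of the marker-fraction correlation
        fx = simulate_cohort(small_config(seed=51, samples_per_cohort=[150, 150]), 0)
        x = ExpressionMatrix(values=fx.expression.values)
        f = fx.true_fractions.to_numpy()
        before = np.array(
            [np.corrcoef(x.values.loc[m], f)[0, 1] for m in fx.marker_probes]
        )
        corrected, _ = pc_correct_skip_genetic(x, fx.genotypes, n_components=20)
        after = np.array(
            [np.corrcoef(corrected.values.loc[m], f)[0, 1] for m in fx.marker_probes]
        )
        assert np.abs(after).mean() < 0.3 * np.abs(before).mean()
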