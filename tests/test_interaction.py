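"""Interaction model: OLS oracle equivalence, sandwich SEs, scan semantics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import statsmodels.api as sm

from ctqtl import (
    cohort_scan,
    fit_interaction,
    fit_main_effect,
    robust_se3,
    MarkerRule,
    build_proxy,
    select_markers,
)

def random_instance(rng, n=30, hetero=False):
    g = rng.integers(0, 3, size=n).astype(float)
    p = rng.normal(size=n)
    scale = 1.0 + (0.8 * np.abs(p) if hetero else 0.0)
    y = 0.4 * g - 0.2 * p + 0.3 * g * p + rng.normal(scale=scale, size=n)
    return y, g, p


class TestFitInteraction:
    def test_exact_generative_identity(self, rng):
        n = 20
        g = rng.integers(0, 3, size=n).astype(float)
        p = rng.normal(size=n)
        res = fit_interaction(g * p, g, p)
        assert res.beta3 == pytest.approx(1.0, abs=1e-10)
        assert res.beta1 == pytest.approx(0.0, abs=1e-10)
        assert res.beta2 == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equation_and_statsmodels_oracles(self, rng):
        y, g, p = random_instance(rng)
        res = fit_interaction(y, g, p)
        # independent brute-force oracle: explicit (X'X)^-1 X'y
        x = np.column_stack([np.ones(len(g)), g, p, g * p])
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        resid = y - x @ beta
        sigma2 = resid @ resid / (len(y) - 4)
        se3 = np.sqrt(sigma2 * np.linalg.inv(x.T @ x)[3, 3])
        assert res.beta1 == pytest.approx(beta[1], abs=1e-8)
        assert res.beta2 == pytest.approx(beta[2], abs=1e-8)
        assert res.beta3 == pytest.approx(beta[3], abs=1e-8)
        assert res.se3_classical == pytest.approx(se3, abs=1e-8)
        # cross-check against statsmodels
        fit = sm.OLS(y, x).fit()
        assert res.beta3 == pytest.approx(fit.params[3], abs=1e-8)
        assert res.se3_classical == pytest.approx(fit.bse[3], abs=1e-8)
        assert res.z3 == pytest.approx(fit.params[3] / fit.bse[3], abs=1e-8)

    def test_constant_genotype_or_proxy_rejected(self, rng):
        y = rng.normal(size=10)
        with pytest.raises(ValueError, match="genotype"):
            fit_interaction(y, np.ones(10), rng.normal(size=10))
        with pytest.raises(ValueError, match="proxy"):
            fit_interaction(y, rng.integers(0, 3, 10).astype(float), np.full(10, 2.0))

    def test_collinear_design_named(self, rng):
        g = rng.integers(0, 3, 20).astype(float)
        with pytest.raises(ValueError, match="collinear.*rs9.*probeX"):
            fit_interaction(rng.normal(size=20), g, 2 * g + 1, snp_id="rs9", probe_id="probeX")

    def test_null_z_scores_are_standard_normal(self, rng):
        zs = []
        for _ in range(2000):
            n = 200
            g = rng.binomial(2, 0.3, n).astype(float)
            p = rng.normal(size=n)
            y = 0.5 * g + rng.normal(size=n)  # main effect, no interaction
            zs.append(fit_interaction(y, g, p).z3)
        zs = np.array(zs)
        assert abs(zs.mean()) < 0.05
        assert 0.9 < zs.var() < 1.1

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 10), st.floats(-5, 5))
    def test_z3_invariances(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        y, g, p = random_instance(rng)
        base = fit_interaction(y, g, p)
        rescaled = fit_interaction(y, g, scale * p + shift)
        assert rescaled.z3 == pytest.approx(base.z3, abs=1e-6)
        shifted = fit_interaction(y, g + shift, p)
        assert shifted.z3 == pytest.approx(base.z3, abs=1e-6)

    def test_allele_flip_negates_interaction_but_keeps_magnitude(self, rng):
        y, g, p = random_instance(rng)
        a = fit_interaction(y, g, p)
        b = fit_interaction(y, 2 - g, p)
        assert b.beta1 == pytest.approx(-a.beta1, abs=1e-8)
        assert b.beta3 == pytest.approx(-a.beta3, abs=1e-8)
        assert abs(b.z3) == pytest.approx(abs(a.z3), abs=1e-8)

    def test_main_effect_reduced_model_matches_statsmodels(self, rng):
        n = 40
        g = rng.integers(0, 3, n).astype(float)
        y = 0.7 * g + rng.normal(size=n)
        beta1, se1, z1 = fit_main_effect(y, g)
        fit = sm.OLS(y, sm.add_constant(g)).fit()
        assert beta1 == pytest.approx(fit.params[1], abs=1e-8)
        assert se1 == pytest.approx(fit.bse[1], abs=1e-8)


class TestRobustSe:
    def test_hc0_matches_hand_sandwich_and_statsmodels(self, rng):
        y, g, p = random_instance(rng, n=12, hetero=True)
        res = fit_interaction(y, g, p)
        se_hc0 = robust_se3(y, g, p, res, estimator="HC0")
        x = np.column_stack([np.ones(12), g, p, g * p])
        xtx_inv = np.linalg.inv(x.T @ x)
        e = y - x @ np.linalg.solve(x.T @ x, x.T @ y)
        cov = xtx_inv @ (x * (e**2)[:, None]).T @ x @ xtx_inv
        assert se_hc0 == pytest.approx(np.sqrt(cov[3, 3]), abs=1e-10)
        fit = sm.OLS(y, x).fit(cov_type="HC0")
        assert se_hc0 == pytest.approx(fit.bse[3], abs=1e-10)
        se_hc3 = robust_se3(y, g, p, res, estimator="HC3")
        fit3 = sm.OLS(y, x).fit(cov_type="HC3")
        assert se_hc3 == pytest.approx(fit3.bse[3], abs=1e-10)

    def test_homoscedastic_large_sample_equivalence(self, rng):
        y, g, p = random_instance(rng, n=5000)
        res = fit_interaction(y, g, p)
        se = robust_se3(y, g, p, res, estimator="HC0")
        assert 0.95 < se / res.se3_classical < 1.05

    def test_classical_and_hc3_z_strongly_correlated_under_mild_heteroscedasticity(self, rng):
        z_classical, z_robust = [], []
        for _ in range(1000):
            y, g, p = random_instance(rng, n=80, hetero=True)
            res = fit_interaction(y, g, p)
            se = robust_se3(y, g, p, res, estimator="HC3")
            z_classical.append(res.z3)
            z_robust.append(res.beta3 / se)
        assert np.corrcoef(z_classical, z_robust)[0, 1] > 0.95


class TestCohortScan:
    @pytest.fixture()
    def scan_setup(self, training_fixture):
        import copy

        config, train, _ = training_fixture
        train = copy.deepcopy(train)  # some tests corrupt genotypes on purpose
        counts = train.cell_counts.set_index("sample_id")["percentage"]
        markers = select_markers(train.expression, counts, MarkerRule(top_n=20))
        proxy = build_proxy(train.expression, markers)
        return train, proxy

    def test_single_pair_and_composition_with_unit_fit(self, scan_setup):
        train, proxy = scan_setup
        pairs = [("rs000001", "probe_00080")]
        results, skips = cohort_scan(
            train.expression, train.genotypes, proxy, pairs, cohort_id="c0"
        )
        assert len(results) == 1 and not skips
        r = results[0]
        g = train.genotypes.values.loc["rs000001"].to_numpy()
        y = train.expression.values.loc["probe_00080"].to_numpy()
        p = proxy.sample_scores.to_numpy()
        unit = fit_interaction(y, g, p, "rs000001", "probe_00080", "c0")
        assert r.beta3 == unit.beta3 and r.z3 == unit.z3

    def test_full_scan_matches_per_pair_fits(self, scan_setup, rng):
        train, proxy = scan_setup
        snps = train.genotypes.snp_ids
        probes = train.expression.probe_ids
        pairs = [(snps[i % len(snps)], probes[(7 * i) % len(probes)]) for i in range(50)]
        results, skips = cohort_scan(
            train.expression, train.genotypes, proxy, pairs, cohort_id="c0"
        )
        assert len(results) + len(skips) == len(pairs)
        for r in results[:10]:
            unit = fit_interaction(
                train.expression.values.loc[r.probe_id].to_numpy(),
                train.genotypes.values.loc[r.snp_id].to_numpy(),
                proxy.sample_scores.to_numpy(),
            )
            assert r.z3 == pytest.approx(unit.z3, abs=1e-12)

    def test_monomorphic_snp_lands_in_skip_log(self, scan_setup):
        train, proxy = scan_setup
        geno = train.genotypes
        geno.values.loc[geno.snp_ids[3]] = 0.0
        results, skips = cohort_scan(
            train.expression, geno, proxy,
            [(geno.snp_ids[3], train.expression.probe_ids[0])],
            cohort_id="c0",
        )
        assert results == []
        assert [s.reason for s in skips] == ["monomorphic_snp"]

    def test_unknown_identifiers_and_missing_dosage_handling(self, scan_setup):
        train, proxy = scan_setup
        geno = train.genotypes
        snp = geno.snp_ids[5]
        geno.values.loc[snp, geno.sample_ids[:4]] = np.nan
        results, skips = cohort_scan(
            train.expression, geno, proxy,
            [
                ("rs_nothere", train.expression.probe_ids[0]),
                (snp, "probe_nothere"),
                (snp, train.expression.probe_ids[0]),
            ],
            cohort_id="c0",
        )
        assert [s.reason for s in skips] == ["missing_snp", "missing_probe"]
        assert len(results) == 1
        assert results[0].n_samples == geno.n_samples - 4

    def test_empty_pair_list_rejected(self, scan_setup):
        train, proxy = scan_setup
        with pytest.raises(ValueError, match="empty"):
            cohort_scan(train.expression, train.genotypes, proxy, [], cohort_id="c0")
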