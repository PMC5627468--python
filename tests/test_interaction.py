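import numpy as np
import pytest

from epiqus import (
    InteractionEffect,
    MainEffect,
    NonEstimableError,
    SimulationConfig,
    bonferroni_threshold,
    encode_pair,
    enumerate_pairs,
    fit_ols,
    generate_cohort,
    interaction_test,
    render_threshold,
    scan_all_pairs,
)


class TestEncodePair:
    def test_carrier_indicators_by_definition(self):
        d1 = np.array([0.0, 1, 2, 0])
        d2 = np.array([0.0, 0, 1, 2])
        enc = encode_pair(d1, d2, "carrier")
        assert enc["only1"].tolist() == [0, 1, 0, 0]
        assert enc["only2"].tolist() == [0, 0, 0, 1]
        assert enc["both"].tolist() == [0, 0, 1, 0]

    def test_all_reference_gives_zero_indicators(self):
        z = np.zeros(5)
        enc = encode_pair(z, z, "carrier")
        assert all(v.sum() == 0 for v in enc.values())

    def test_additive_product_column(self):
        enc = encode_pair(np.array([1.0, 2]), np.array([2.0, 1]), "additive")
        assert enc["snp1_x_snp2"].tolist() == [2.0, 2.0]


class TestFitOls:
    def test_exact_linear_fit(self):
        x = np.arange(10, dtype=float)
        y = 2 + 3 * x
        fit = fit_ols(y, np.column_stack([np.ones(10), x]), ["b0", "b1"])
        np.testing.assert_allclose(fit.params, [2.0, 3.0], atol=1e-10)
        np.testing.assert_allclose(fit.cov, 0.0, atol=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        X = np.column_stack([np.ones(50), rng.standard_normal((50, 3))])
        y = rng.standard_normal(50)
        fit = fit_ols(y, X)
        # independent brute-force oracle
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ y
        resid = y - X @ beta
        s2 = resid @ resid / (50 - 4)
        np.testing.assert_allclose(fit.params, beta, rtol=1e-8)
        np.testing.assert_allclose(fit.cov, s2 * XtX_inv, rtol=1e-8)
        assert fit.residual_df == 46

    def test_duplicated_column_non_estimable(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(30)
        X = np.column_stack([np.ones(30), x, x])
        with pytest.raises(NonEstimableError, match="collinear"):
            fit_ols(rng.standard_normal(30), X, ["b0", "x", "x_dup"])

    def test_more_terms_than_samples_non_estimable(self):
        with pytest.raises(NonEstimableError):
            fit_ols(np.zeros(3), np.eye(3))


def _balanced_cells(cell_means, reps=10):
    """Phenotype with exact carriage-cell means (neither, only1, only2, both)."""
    d1 = np.repeat([0.0, 1.0, 0.0, 1.0], reps)
    d2 = np.repeat([0.0, 0.0, 1.0, 1.0], reps)
    y = np.repeat(np.asarray(cell_means, dtype=float), reps)
    return d1, d2, y


class TestInteractionTest:
    def test_saturated_cell_means_recover_exact_contrast(self):
        # beta_observed = 10, beta_SNP1 = 3, beta_SNP2 = 4 -> interaction 3
        d1, d2, y = _balanced_cells([100, 103, 104, 110])
        res = interaction_test(d1, d2, y, covariates=None)
        assert res.estimable
        assert res.beta_interaction == pytest.approx(3.0, abs=1e-10)
        assert res.beta_observed == pytest.approx(10.0, abs=1e-10)
        assert res.beta_snp1 == pytest.approx(3.0, abs=1e-10)
        assert res.beta_snp2 == pytest.approx(4.0, abs=1e-10)
        assert res.cell_counts == (10, 10, 10, 10)

    def test_planted_interaction_recovered_within_uncertainty(self):
        cfg = SimulationConfig(
            n_samples=2000, seed=21, missing_rate=0.0,
            snp_effects=[MainEffect("rs9340799", 3.0), MainEffect("rs3736228", -2.0)],
            interaction_effects=[InteractionEffect("rs9340799", "rs3736228", 8.0)],
        )
        g, c, p = generate_cohort(cfg)
        res = interaction_test(
            g.column("rs9340799"), g.column("rs3736228"), p, c
        )
        assert res.estimable
        assert abs(res.beta_interaction - 8.0) < 3 * res.se
        assert res.ci_low <= res.beta_interaction <= res.ci_high

    def test_contrast_equals_product_term_coefficient(self, small_cohort):
        """The (-1,-1,+1) cell contrast is algebraically the product-term slope."""
        _, (g, c, p) = small_cohort
        d1, d2 = g.column("rs9340799"), g.column("rs3736228")
        res = interaction_test(d1, d2, p, c)
        # reparameterized model: carrier1, carrier2 and their product
        c1, c2 = (d1 >= 1).astype(float), (d2 >= 1).astype(float)
        X = np.column_stack([np.ones(len(d1)), c.as_array(), c1, c2, c1 * c2])
        fit = fit_ols(p.bua, X)
        assert res.beta_interaction == pytest.approx(fit.params[-1], abs=1e-8)
        assert res.se == pytest.approx(np.sqrt(fit.cov[-1, -1]), abs=1e-8)

    def test_symmetric_in_pair_order(self, small_cohort):
        _, (g, c, p) = small_cohort
        d1, d2 = g.column("rs9340799"), g.column("rs3736228")
        r12 = interaction_test(d1, d2, p, c)
        r21 = interaction_test(d2, d1, p, c)
        assert r12.beta_interaction == pytest.approx(r21.beta_interaction, abs=1e-12)
        assert r12.se == pytest.approx(r21.se, abs=1e-12)
        assert r12.p_value == pytest.approx(r21.p_value, abs=1e-12)

    def test_empty_cell_flagged_non_estimable(self):
        rng = np.random.default_rng(3)
        n = 120
        d1 = np.zeros(n)  # nobody carries SNP1
        d2 = rng.binomial(2, 0.3, n).astype(float)
        y = rng.normal(80, 10, n)
        res = interaction_test(d1, d2, y, covariates=None)
        assert not res.estimable
        assert "carriage cell" in res.reason
        assert np.isnan(res.p_value)

    def test_covariates_actually_enter_the_fit(self, small_cohort):
        """Permuting an active covariate must change the estimate."""
        cfg, (g, c, p) = small_cohort
        d1, d2 = g.column("rs9340799"), g.column("rs3736228")
        base = interaction_test(d1, d2, p, c)
        rng = np.random.default_rng(0)
        shuffled = c.data.copy()
        shuffled["bmi"] = rng.permutation(shuffled["bmi"].to_numpy())
        from epiqus import CovariateTable

        c2 = CovariateTable(sample_ids=list(c.sample_ids), data=shuffled)
        perm = interaction_test(d1, d2, p, c2)
        assert perm.beta_interaction != pytest.approx(
            base.beta_interaction, abs=1e-6
        )

    def test_additive_coding_product_term(self, small_cohort):
        _, (g, c, p) = small_cohort
        res = interaction_test(
            g.column("rs9340799"), g.column("rs3736228"), p, c, coding="additive"
        )
        assert res.estimable and np.isfinite(res.p_value)


class TestMultiplicity:
    @pytest.mark.parametrize("k, expected", [(30, 435), (2, 1), (1, 0)])
    def test_pair_counts(self, k, expected):
        rsids = [f"rs{j}" for j in range(k)]
        pairs = enumerate_pairs(rsids)
        assert len(pairs) == expected
        assert len(set(pairs)) == expected  # each pair exactly once

    def test_pairs_follow_panel_order(self):
        assert enumerate_pairs(["a", "b", "c"]) == [
            ("a", "b"), ("a", "c"), ("b", "c")
        ]

    def test_bonferroni_values(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        thr = bonferroni_threshold(0.05, 435)
        assert thr == pytest.approx(0.05 / 435, rel=1e-12)
        assert render_threshold(thr) == "0.0001"
        assert render_threshold(0.05) == "0.05"

    def test_bonferroni_domain_errors(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)


class TestScan:
    def test_scan_row_count_and_ordering(self, small_cohort):
        _, (g, c, p) = small_cohort
        sub = g.subset(g.rsids[:8])
        scan = scan_all_pairs(sub, p, c)
        assert scan.n_pairs == len(scan.results) == 28
        ps = [r.p_value for r in scan.results if r.estimable]
        assert ps == sorted(ps)

    def test_planted_strong_interaction_ranks_first(self):
        cfg = SimulationConfig(
            n_samples=2000, seed=31, missing_rate=0.0,
            interaction_effects=[InteractionEffect("rs9340799", "rs3736228", 15.0)],
        )
        g, c, p = generate_cohort(cfg)
        sub = g.subset(
            ["rs9340799", "rs3736228", "rs11898505", "rs7741021", "rs4355801",
             "rs597319", "rs1805034", "rs851054"]
        )
        scan = scan_all_pairs(sub, p, c)
        top = scan.results[0]
        assert {top.rsid1, top.rsid2} == {"rs9340799", "rs3736228"}

    def test_non_estimable_pairs_kept_at_end(self, small_cohort):
        _, (g, c, p) = small_cohort
        import copy

        sub = copy.deepcopy(g.subset(g.rsids[:4]))
        sub.dosages[:, 0] = 0.0  # monomorphic -> all its pairs non-estimable
        scan = scan_all_pairs(sub, p, c)
        assert scan.n_pairs == 6 and scan.n_estimable == 3
        tail = scan.results[3:]
        assert all(not r.estimable for r in tail)
        assert all(r.reason for r in tail)
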