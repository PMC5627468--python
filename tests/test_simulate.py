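import numpy as np
import pytest

from epiqus import (
    ConfigError,
    InteractionEffect,
    MainEffect,
    SimulationConfig,
    SnpMarker,
    UnattainableLdError,
    generate_cohort,
    genotype_r2,
    hwe_chi_square,
    max_attainable_r2,
    simulate_covariates,
    simulate_genotypes,
    simulate_phenotype,
)
from epiqus.qc import genotype_counts


def _mini_panel(mafs):
    return [
        SnpMarker(f"rs{j}", "1", f"G{j}", "A", "C", m) for j, m in enumerate(mafs)
    ]


class TestGenotypes:
    def test_maf_zero_marker_is_all_reference(self):
        cfg = SimulationConfig(
            n_samples=200, seed=1, panel=_mini_panel([0.0, 0.3]),
            ld_pairs=[], missing_rate=0.0,
        )
        g = simulate_genotypes(cfg)
        assert (g.column("rs0") == 0).all()

    def test_half_maf_marker_matches_binomial_expectation(self):
        cfg = SimulationConfig(
            n_samples=100_000, seed=2, panel=_mini_panel([0.5]),
            ld_pairs=[], missing_rate=0.0,
        )
        d = simulate_genotypes(cfg).column("rs0")
        assert 0.99 <= d.mean() <= 1.01
        props = np.array(genotype_counts(d)) / len(d)
        np.testing.assert_allclose(props, [0.25, 0.5, 0.25], atol=0.01)

    def test_ld_pair_calibrated_to_target(self):
        cfg = SimulationConfig(
            n_samples=10_000, seed=3, panel=_mini_panel([0.3, 0.3]),
            ld_pairs=[("rs0", "rs1", 0.95)], missing_rate=0.0,
        )
        g = simulate_genotypes(cfg)
        r2 = genotype_r2(g.column("rs0"), g.column("rs1"))
        assert 0.92 <= r2 <= 0.98

    def test_ld_markers_stay_in_hwe(self):
        cfg = SimulationConfig(
            n_samples=20_000, seed=4, panel=_mini_panel([0.25, 0.25]),
            ld_pairs=[("rs0", "rs1", 0.9)], missing_rate=0.0,
        )
        g = simulate_genotypes(cfg)
        for rsid in ("rs0", "rs1"):
            res = hwe_chi_square(*genotype_counts(g.column(rsid)))
            assert res.p > 1e-4  # no gross HWE violation from the copula

    def test_unattainable_ld_target_reports_maximum(self):
        # MAF 0.4 vs 0.05: genotype correlation is capped far below 0.9
        cap = max_attainable_r2(0.4, 0.05)
        assert cap < 0.3
        cfg = SimulationConfig(
            n_samples=100, seed=5, panel=_mini_panel([0.4, 0.05]),
            ld_pairs=[("rs0", "rs1", 0.9)], missing_rate=0.0,
        )
        with pytest.raises(UnattainableLdError, match="maximum achievable"):
            simulate_genotypes(cfg)

    def test_missingness_rate_honoured(self):
        cfg = SimulationConfig(
            n_samples=5000, seed=6, panel=_mini_panel([0.3, 0.2]),
            ld_pairs=[], missing_rate=0.1,
        )
        g = simulate_genotypes(cfg)
        assert 0.08 <= np.isnan(g.dosages).mean() <= 0.12

    def test_realized_maf_converges_to_target(self):
        cfg = SimulationConfig(n_samples=10_000, seed=7, missing_rate=0.0)
        g = simulate_genotypes(cfg)
        from epiqus import compute_maf

        for m in g.markers:
            assert abs(compute_maf(g.column(m.rsid)) - m.panel_maf) < 0.02


class TestCovariates:
    def test_default_cohort_female_count_near_expectation(self):
        c = simulate_covariates(SimulationConfig(seed=8))
        females = c.data["sex"].sum()
        assert abs(females - 400) <= 40

    def test_zero_variance_age_is_constant(self):
        c = simulate_covariates(SimulationConfig(n_samples=50, seed=9, age_sd=0.0))
        assert (c.data["age"] == 20.41).all()

    def test_moments_and_bounds(self):
        c = simulate_covariates(SimulationConfig(n_samples=5000, seed=10))
        assert c.data["age"].mean() == pytest.approx(20.41, abs=0.2)
        assert c.data["age"].std() == pytest.approx(2.36, abs=0.2)
        assert (c.data["physical_activity"] >= 0).all()
        assert (c.data["calcium_intake"] >= 0).all()
        assert (c.data["bmi"] > 10).all()


class TestPhenotype:
    def test_no_effects_no_noise_gives_intercept(self):
        cfg = SimulationConfig(
            n_samples=30, seed=11, panel=_mini_panel([0.3]), ld_pairs=[],
            missing_rate=0.0, noise_sd=0.0, covariate_effects={}, intercept=75.0,
        )
        g = simulate_genotypes(cfg)
        c = simulate_covariates(cfg)
        p = simulate_phenotype(g, c, cfg)
        np.testing.assert_allclose(p.bua, 75.0)

    def test_carrier_interaction_shifts_double_carriers_exactly(self):
        cfg = SimulationConfig(
            n_samples=500, seed=12, panel=_mini_panel([0.4, 0.4]), ld_pairs=[],
            missing_rate=0.0, noise_sd=0.0, covariate_effects={}, intercept=0.0,
            snp_effects=[MainEffect("rs0", 3.0), MainEffect("rs1", 4.0)],
            interaction_effects=[InteractionEffect("rs0", "rs1", 8.0)],
        )
        g = simulate_genotypes(cfg)
        c = simulate_covariates(cfg)
        y = simulate_phenotype(g, c, cfg).bua
        c1, c2 = g.column("rs0") >= 1, g.column("rs1") >= 1
        assert y[~c1 & ~c2].mean() == pytest.approx(0.0)
        assert y[c1 & ~c2].mean() == pytest.approx(3.0)
        assert y[~c1 & c2].mean() == pytest.approx(4.0)
        assert y[c1 & c2].mean() == pytest.approx(15.0)  # 3 + 4 + 8

    def test_unknown_effect_rsid_rejected(self):
        cfg = SimulationConfig(
            n_samples=20, seed=13, panel=_mini_panel([0.3]), ld_pairs=[],
            snp_effects=[MainEffect("rs_nonexistent", 1.0)],
        )
        with pytest.raises(ConfigError, match="rs_nonexistent"):
            simulate_genotypes(cfg)


class TestCohort:
    def test_default_cohort_dimensions(self):
        g, c, p = generate_cohort(SimulationConfig(seed=14))
        assert len(g.sample_ids) == 575
        assert len(g.markers) == 32
        assert g.sample_ids == c.sample_ids == p.sample_ids

    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(n_samples=60, seed=15)
        generate_cohort(cfg, out_dir=tmp_path / "a")
        generate_cohort(cfg, out_dir=tmp_path / "b")
        for name in ("genotypes.tsv", "covariates.tsv", "phenotype.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_genotypes_invariant_to_phenotype_parameters(self):
        base = SimulationConfig(n_samples=80, seed=16, missing_rate=0.0)
        from dataclasses import replace

        alt = replace(base, noise_sd=1.0, intercept=500.0)
        g1 = generate_cohort(base).genotypes
        g2 = generate_cohort(alt).genotypes
        np.testing.assert_array_equal(g1.dosages, g2.dosages)

    def test_planted_effects_unbiased_recovery(self):
        """Mean estimate over replicates stays near the planted value."""
        from epiqus import interaction_test

        estimates = []
        for rep in range(40):
            cfg = SimulationConfig(
                n_samples=2000, seed=1000 + rep, missing_rate=0.0,
                interaction_effects=[
                    InteractionEffect("rs9340799", "rs3736228", 8.0)
                ],
            )
            g, c, p = generate_cohort(cfg)
            res = interaction_test(
                g.column("rs9340799"), g.column("rs3736228"), p, c
            )
            estimates.append(res.beta_interaction)
        assert np.mean(estimates) == pytest.approx(8.0, abs=1.0)
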