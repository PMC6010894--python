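"""Synthetic-cohort generator: HWE genotypes, log-normal AFP, rare outcome."""

import math

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal
from scipy.special import expit
from scipy.stats import chisquare

import gcorrect as gc


class TestGenotypes:
    def test_degenerate_frequency_gives_all_zero(self, rng):
        dose = gc.simulate_genotypes(200, [gc.SnpSpec("rs_fixed", 0.0, 1.5)], rng)
        assert (dose["rs_fixed"] == 0).all()

    def test_invalid_frequency_names_snp(self):
        with pytest.raises(ValueError, match="rs_bad"):
            gc.SnpSpec("rs_bad", 1.5, 1.1)

    def test_sample_frequency_within_three_se(self, rng):
        n = 100_000
        dose = gc.simulate_genotypes(n, [gc.SnpSpec("rs1", 0.33, 1.0)], rng)
        p_hat = dose["rs1"].mean() / 2
        se = math.sqrt(0.33 * 0.67 / (2 * n))
        assert abs(p_hat - 0.33) <= 3 * se

    def test_same_seed_identical_matrices(self):
        panel = gc.DEFAULT_SNP_PANEL
        d1 = gc.simulate_genotypes(5000, panel, np.random.default_rng(9))
        d2 = gc.simulate_genotypes(5000, panel, np.random.default_rng(9))
        assert_frame_equal(d1, d2)

    @pytest.mark.parametrize("seed", range(5))
    def test_hwe_goodness_of_fit(self, seed):
        n = 100_000
        p = 0.47
        dose = gc.simulate_genotypes(n, [gc.SnpSpec("rs1", p, 1.0)],
                                     np.random.default_rng(seed))
        obs = [(dose["rs1"] == k).sum() for k in (0, 1, 2)]
        exp = [n * w for w in gc.hwe_weights(p)]
        assert chisquare(obs, exp).pvalue > 0.001


class TestAfp:
    def test_no_variation_collapses_to_median(self, rng):
        panel = [gc.SnpSpec("rs1", 0.33, 1.0)]
        dose = gc.simulate_genotypes(100, panel, rng)
        draws = gc.simulate_afp(dose, panel, afp_median=2.70,
                                log_noise_sd=1e-12, detection_limit=0.005,
                                rng=rng)
        np.testing.assert_allclose(draws.latent, 2.70, rtol=1e-9)

    def test_detection_floor_is_exact(self, rng):
        panel = [gc.SnpSpec("rs1", 0.33, 1.0)]
        dose = gc.simulate_genotypes(5000, panel, rng)
        draws = gc.simulate_afp(dose, panel, afp_median=0.01,
                                log_noise_sd=2.0, detection_limit=0.005,
                                rng=rng)
        floored = draws.latent < 0.005
        assert floored.any()
        assert (draws.observed[floored] == 0.005).all()
        assert (draws.observed >= 0.005).all()

    def test_log_regression_recovers_slope(self):
        rng = np.random.default_rng(3)
        panel = [gc.SnpSpec("rs1", 0.33, 1.08), gc.SnpSpec("rs2", 0.47, 1.10)]
        dose = gc.simulate_genotypes(50_000, panel, rng)
        draws = gc.simulate_afp(dose, panel, 2.70, 1.0, 1e-300, rng)
        for snp in panel:
            a_hat, se = gc.fit_allelic_effect(dose[snp.snp_id], draws.observed)
            assert abs(math.log(a_hat) - math.log(snp.a)) <= 3 * se

    def test_genetic_factor_decomposition(self, rng):
        panel = gc.DEFAULT_SNP_PANEL
        dose = gc.simulate_genotypes(1000, panel, rng)
        draws = gc.simulate_afp(dose, panel, 2.70, 1.0, 0.005, rng)
        np.testing.assert_allclose(draws.latent,
                                   draws.signal * draws.genetic_factor,
                                   rtol=1e-12)

    def test_rejects_nonpositive_parameters(self, rng):
        panel = [gc.SnpSpec("rs1", 0.33, 1.0)]
        dose = gc.simulate_genotypes(10, panel, rng)
        with pytest.raises(ValueError):
            gc.simulate_afp(dose, panel, -1.0, 1.0, 0.005, rng)
        with pytest.raises(ValueError):
            gc.simulate_afp(dose, panel, 2.7, 0.0, 0.005, rng)


class TestOutcome:
    def test_intercept_hits_marginal_to_1e6(self, rng):
        x = 2.7 * np.exp(rng.normal(0, 1, 50_000))
        lin = math.log(5.0) * x / 10
        alpha = gc.solve_marginal_intercept(lin, 0.00581)
        assert abs(float(np.mean(expit(alpha + lin))) - 0.00581) < 1e-6

    def test_null_or_keeps_outcome_independent(self, rng):
        x = 2.7 * np.exp(rng.normal(0, 1, 100_000))
        y, _ = gc.simulate_outcome(x, 1.0, 0.05, rng)
        se = math.sqrt(0.05 * 0.95 / len(x))
        assert abs(y.mean() - 0.05) <= 3 * se
        # no association: point-biserial correlation is tiny
        assert abs(np.corrcoef(x, y)[0, 1]) < 0.01

    def test_case_count_matches_rare_incidence(self, rng):
        x = 2.7 * np.exp(rng.normal(0, 1, 100_000))
        y, _ = gc.simulate_outcome(x, 5.0, 0.00581, rng)
        se = math.sqrt(100_000 * 0.00581 * (1 - 0.00581))
        assert abs(y.sum() - 581) <= 3 * se

    def test_unattainable_marginal_rejected(self):
        with pytest.raises(ValueError):
            gc.solve_marginal_intercept(np.zeros(10), 1.0)


class TestCovariates:
    def test_default_marginals_recovered(self):
        rng = np.random.default_rng(14)
        n = 100_000
        cov = gc.simulate_covariates(n, dict(gc.DEFAULT_COVARIATES), rng)
        se_smoke = math.sqrt(0.303 * 0.697 / n)
        assert abs(cov["smoking"].mean() - 0.303) <= 3 * se_smoke
        assert abs(cov["age"].mean() - 62.09) <= 3 * 7.78 / math.sqrt(n)
        assert abs(cov["age"].std(ddof=1) - 7.78) <= 3 * 7.78 / math.sqrt(2 * n)
        se_male = math.sqrt(0.469 * 0.531 / n)
        assert abs((cov["sex"] == "male").mean() - 0.469) <= 3 * se_male

    def test_zero_prevalence_all_zero(self, rng):
        cov = gc.simulate_covariates(500, {"smoking": 0.0}, rng)
        assert (cov["smoking"] == 0).all()

    def test_unknown_covariate_rejected(self, rng):
        with pytest.raises(ValueError, match="shoe_size"):
            gc.simulate_covariates(10, {"shoe_size": 0.5}, rng)


class TestCohortPipeline:
    def test_same_seed_bit_identical(self):
        cfg = gc.SimulationConfig(n_participants=3000, genotype_missing_rate=0.05)
        a = gc.simulate_cohort(cfg, seed=77)
        b = gc.simulate_cohort(cfg, seed=77)
        assert_frame_equal(a.cohort, b.cohort)
        assert_frame_equal(a.truth, b.truth)
        assert a.intercept == b.intercept

    def test_cohort_contract(self):
        sim = gc.simulate_cohort(gc.SimulationConfig(n_participants=500), seed=1)
        df = sim.cohort
        assert not df["id"].duplicated().any()
        assert (df["afp_ng_ml"] >= 0.005).all()
        assert df["hcc"].isin([0, 1]).all()
        for snp in gc.DEFAULT_SNP_PANEL:
            assert df[snp.snp_id].dropna().isin([0, 1, 2]).all()

    def test_covariate_log_odds_shift_incidence_structure(self):
        cfg = gc.SimulationConfig(
            n_participants=30_000, baseline_incidence=0.05,
            covariate_log_odds={"smoking": 1.5})
        sim = gc.simulate_cohort(cfg, seed=8)
        df = sim.cohort
        rate_s = df.loc[df.smoking == 1, "hcc"].mean()
        rate_n = df.loc[df.smoking == 0, "hcc"].mean()
        assert rate_s > rate_n
        # marginal still calibrated
        assert abs(df["hcc"].mean() - 0.05) <= 3 * math.sqrt(0.05 * 0.95 / len(df))


class TestCohortIO:
    def test_round_trip_lossless(self, tmp_path):
        cfg = gc.SimulationConfig(n_participants=400, genotype_missing_rate=0.1)
        sim = gc.simulate_cohort(cfg, seed=2)
        path = tmp_path / "cohort.tsv"
        gc.write_cohort(sim.cohort, path)
        back = gc.read_cohort(path)
        assert_frame_equal(back, sim.cohort, check_dtype=False)

    def test_bad_dosage_names_row(self, tmp_path):
        sim = gc.simulate_cohort(gc.SimulationConfig(n_participants=5), seed=3)
        df = sim.cohort.copy()
        df.loc[2, "rs12506899"] = 3
        path = tmp_path / "bad.tsv"
        gc.write_cohort(df, path)
        with pytest.raises(ValueError, match="row 3"):
            gc.read_cohort(path)

    def test_duplicate_id_rejected(self, tmp_path):
        sim = gc.simulate_cohort(gc.SimulationConfig(n_participants=4), seed=3)
        df = sim.cohort.copy()
        df.loc[3, "id"] = df.loc[0, "id"]
        path = tmp_path / "dup.tsv"
        gc.write_cohort(df, path)
        with pytest.raises(ValueError, match="duplicated id"):
            gc.read_cohort(path)

    def test_below_detection_limit_accepted_with_warning(self, tmp_path, caplog):
        sim = gc.simulate_cohort(gc.SimulationConfig(n_participants=5), seed=3)
        df = sim.cohort.copy()
        df.loc[1, "afp_ng_ml"] = 0.001
        path = tmp_path / "low.tsv"
        gc.write_cohort(df, path)
        with caplog.at_level("WARNING"):
            back = gc.read_cohort(path)
        assert len(back) == 5
        assert "detection limit" in caplog.text

    def test_non_numeric_afp_rejected(self, tmp_path):
        path = tmp_path / "text.tsv"
        path.write_text("id\tafp_ng_ml\thcc\nP1\t2.5\t0\nP2\tlots\t0\n")
        with pytest.raises(ValueError, match="row 2"):
            gc.read_cohort(path)


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        dict(n_participants=0), dict(log_noise_sd=0.0),
        dict(baseline_incidence=0.0), dict(baseline_incidence=1.0),
        dict(true_or_per_10=-1.0), dict(detection_limit=0.0),
        dict(covariate_prevalences={"nope": 0.5}),
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            gc.SimulationConfig(**kwargs)

    def test_yaml_round_trip(self, tmp_path):
        import yaml
        cfg = gc.SimulationConfig(n_participants=123, true_or_per_10=2.0)
        path = tmp_path / "sim.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        back = gc.SimulationConfig.from_yaml(path)
        assert back == cfg
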