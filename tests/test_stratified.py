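import numpy as np
import pandas as pd
import pytest
from scipy import stats

import diurnalgwas as dg
from diurnalgwas.linmod import NotTestableError
from diurnalgwas.stratified import (
    StrataSpec,
    sleep_interaction_test,
    stratified_effect_by_trait,
    stratify,
    variance_explained_by_time,
    window_contrast,
)


def _adj(samples):
    out = samples.copy()
    log = np.log(out["glucose_raw"])
    out["glucose_adj"] = log - log.mean()
    return out


class TestStratify:
    def test_morning_sample_with_enough_fasting(self):
        df = pd.DataFrame({"draw_time": [10 * 3600 + 59 * 60], "fasting_hours": [9.0]})
        masks, _ = stratify(df, StrataSpec(fasting_min_hours=8))
        assert masks["morning"][0] and not masks["evening"][0]

    def test_midday_sample_unassigned(self):
        df = pd.DataFrame({"draw_time": [12 * 3600], "fasting_hours": [12.0]})
        masks, n_excluded = stratify(df, StrataSpec())
        assert not masks["morning"][0] and not masks["evening"][0]
        assert n_excluded == 1

    def test_window_fractions_on_uniform_draws(self, rng):
        n = 40_000
        df = pd.DataFrame(
            {"draw_time": rng.uniform(8 * 3600, 20 * 3600, n), "fasting_hours": np.ones(n)}
        )
        masks, n_excluded = stratify(df, StrataSpec())
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(masks["morning"].mean() - 3 / 12) < 3 * se
        assert abs(masks["evening"].mean() - 3 / 12) < 3 * se
        assert masks["morning"].sum() + masks["evening"].sum() + n_excluded == n

    def test_invalid_windows_rejected(self):
        with pytest.raises(ValueError):
            StrataSpec(morning_end=18, evening_start=17)


class TestWindowContrast:
    def test_mtnr1b_like_sign_reversal_flag(self, mtnr1b_cohort):
        _, geno, samples = mtnr1b_cohort
        res, flag = window_contrast(geno.dosages[:, 0], samples)
        assert res["morning"].beta > 0
        assert res["evening"].beta < 0
        assert flag is True

    def test_constant_effect_rarely_flips(self):
        cfg = dg.scenario("constant_effect", n_samples=20_000, seed=41)
        geno, samples = dg.simulate_cohort(cfg)
        samples = _adj(samples)
        res, flag = window_contrast(geno.dosages[:, 0], samples)
        # strong constant effect: both windows positive
        assert flag is False

    def test_zero_effect_p_not_extreme(self, null_cohort):
        _, geno, samples = null_cohort
        res, _ = window_contrast(geno.dosages[:, 0], samples)
        for r in res.values():
            assert r.p > 1e-4

    def test_small_window_dropped(self, mtnr1b_cohort):
        _, geno, samples = mtnr1b_cohort
        res, flag = window_contrast(
            geno.dosages[:, 0],
            samples,
            spec=StrataSpec(fasting_min_hours=23.9),  # nobody fasts this long
        )
        assert res == {} and flag is None

    def test_locality_evening_perturbation_leaves_morning_identical(self, mtnr1b_cohort):
        _, geno, samples = mtnr1b_cohort
        res1, _ = window_contrast(geno.dosages[:, 0], samples)
        perturbed = samples.copy()
        evening = perturbed["draw_time"] / 3600 >= 17
        perturbed.loc[evening, "glucose_adj"] = (
            perturbed.loc[evening, "glucose_adj"] + 5.0
        )
        res2, _ = window_contrast(geno.dosages[:, 0], perturbed)
        assert res1["morning"].beta == res2["morning"].beta
        assert res1["morning"].se == res2["morning"].se


class TestSleepInteraction:
    def test_binary_trait_joint_equals_z_squared(self, rng):
        n = 4000
        samples = pd.DataFrame(
            {
                "glucose_adj": rng.standard_normal(n),
                "trait": rng.choice(["no", "yes"], n),
            }
        )
        g = rng.binomial(2, 0.3, n).astype(float)
        res = sleep_interaction_test(g, samples, "trait")
        assert res["df"] == 1
        fit = res["fit"]
        z = fit.params["G:trait_yes"] / fit.bse["G:trait_yes"]
        assert res["chi2"] == pytest.approx(z**2, rel=1e-10)

    def test_single_level_trait_not_testable(self, rng):
        n = 200
        samples = pd.DataFrame(
            {"glucose_adj": rng.standard_normal(n), "trait": ["same"] * n}
        )
        with pytest.raises(NotTestableError):
            sleep_interaction_test(rng.binomial(2, 0.3, n).astype(float), samples, "trait")

    def test_no_interaction_scenario_is_null(self, mtnr1b_cohort):
        """Sleep traits drawn independently of genotype: the G x trait test
        should not reject beyond chance."""
        _, geno, samples = mtnr1b_cohort
        masks, _ = stratify(samples, StrataSpec())
        ps = []
        for trait in ("chronotype", "insomnia", "napping", "daytime_dozing"):
            for window in ("morning", "evening"):
                res = sleep_interaction_test(
                    geno.dosages[:, 0], samples, trait, window_mask=masks[window]
                )
                ps.append(res["p_interaction"])
        assert min(ps) > 0.05 / len(ps)  # no Bonferroni-significant interaction

    def test_simulated_interaction_detected(self):
        """Doubling the diurnal amplitude in one insomnia level is detected
        in the morning window at n = 50k (configured power > 0.8)."""
        rejections = 0
        for seed in range(5):
            cfg = dg.scenario(
                "mtnr1b_like",
                n_samples=50_000,
                seed=500 + seed,
                sleep_amp_factor={"insomnia": {"usually": 2.0}},
            )
            geno, samples = dg.simulate_cohort(cfg)
            samples = _adj(samples)
            masks, _ = stratify(samples, StrataSpec())
            res = sleep_interaction_test(
                geno.dosages[:, 0], samples, "insomnia", window_mask=masks["morning"]
            )
            rejections += res["p_interaction"] < 0.05
        assert rejections >= 3


class TestStratifiedByTrait:
    def test_consistent_morning_effects_without_interaction(self, mtnr1b_cohort):
        _, geno, samples = mtnr1b_cohort
        table = stratified_effect_by_trait(geno.dosages[:, 0], samples, "chronotype")
        morning = table[table["window"] == "morning"]
        assert len(morning) >= 3
        betas = morning["beta"].to_numpy()
        ses = morning["se"].to_numpy()
        for i in range(len(betas)):
            for j in range(i + 1, len(betas)):
                assert abs(betas[i] - betas[j]) < 3 * np.hypot(ses[i], ses[j])

    def test_sparse_level_skipped(self, rng):
        n = 3000
        samples = pd.DataFrame(
            {
                "glucose_adj": rng.standard_normal(n),
                "draw_time": rng.uniform(8 * 3600, 20 * 3600, n),
                "fasting_hours": np.ones(n),
                "trait": pd.Categorical(
                    ["common"] * (n - 5) + ["rare"] * 5, categories=["common", "rare"]
                ),
            }
        )
        table = stratified_effect_by_trait(
            rng.binomial(2, 0.3, n).astype(float), samples, "trait"
        )
        assert set(table["trait_level"]) == {"common"}


class TestVarianceExplained:
    def test_time_independent_phenotype_near_zero(self, rng):
        n = 20_000
        out = variance_explained_by_time(
            rng.standard_normal(n), rng.uniform(0, 86400, n)
        )
        assert out["r2_all"] < 2 * 24 / n * 10  # small multiple of k/n

    def test_deterministic_bin_function_gives_r2_one(self, rng):
        n = 5000
        s = rng.uniform(0, 86400, n)
        hour = (s / 3600).astype(int)
        y = np.take(np.sin(np.arange(24)), hour)
        out = variance_explained_by_time(y, s)
        assert out["r2_all"] == pytest.approx(1.0, abs=1e-10)

    def test_calibration_scenario_recovers_ten_percent(self):
        cfg = dg.scenario("variance_calibration", n_samples=60_000, seed=77)
        geno, samples = dg.simulate_cohort(cfg)
        out = variance_explained_by_time(
            np.log(samples["glucose_raw"]),
            samples["draw_time"],
            samples["fasting_hours"],
        )
        assert out["r2_all"] == pytest.approx(0.10, abs=0.02)
        assert out["r2_fasting"] == pytest.approx(0.10, abs=0.02)

    def test_degenerate_phenotype_rejected(self, rng):
        with pytest.raises(ValueError, match="degenerate"):
            variance_explained_by_time(np.ones(500), rng.uniform(0, 86400, 500))

    def test_small_n_rejected(self, rng):
        with pytest.raises(ValueError, match="n >= 100"):
            variance_explained_by_time(rng.standard_normal(50), rng.uniform(0, 86400, 50))
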