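import numpy as np
import pandas as pd
import pytest
from scipy import stats

import diurnalgwas as dg
from diurnalgwas.cosinor import (
    CosinorScan,
    acrophase_hours,
    cosinor_test,
    effect_at_time,
    encode_time,
)


class TestEncodeTime:
    @pytest.mark.parametrize(
        "t,expected",
        [
            (0.0, (0.0, 1.0)),  # midnight
            (0.25, (1.0, 0.0)),  # 06:00
            (0.75, (-1.0, 0.0)),  # 18:00
        ],
    )
    def test_cardinal_times(self, t, expected):
        s, c = encode_time([t])
        assert s[0] == pytest.approx(expected[0], abs=1e-12)
        assert c[0] == pytest.approx(expected[1], abs=1e-12)

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5, np.nan])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            encode_time([bad])


class TestCosinorTest:
    def test_noiseless_recovery(self, rng):
        n = 2000
        t = rng.uniform(0, 1, n)
        g = rng.binomial(2, 0.3, n).astype(float)
        y = 1.0 + 0.2 * np.sin(2 * np.pi * t) + g * (0.05 * np.sin(2 * np.pi * t))
        res = cosinor_test(g, y, t)
        assert res.beta_sin == pytest.approx(0.05, abs=1e-8)
        assert res.beta_cos == pytest.approx(0.0, abs=1e-8)
        assert res.beta_main == pytest.approx(0.0, abs=1e-8)

    def test_monomorphic_variant_rejected(self, rng):
        n = 100
        with pytest.raises(ValueError, match="monomorphic"):
            cosinor_test(np.zeros(n), rng.standard_normal(n), rng.uniform(0, 1, n))

    def test_separate_mode_matches_single_interaction_fits(self, rng):
        n = 3000
        t = rng.uniform(1 / 3, 5 / 6, n)
        g = rng.binomial(2, 0.3, n).astype(float)
        y = g * 0.04 * np.sin(2 * np.pi * t) + rng.normal(0, 0.5, n)
        res = cosinor_test(g, y, t, mode="separate")
        assert np.isnan(res.p_joint)
        assert 0 < res.p_sin <= 1 and 0 < res.p_cos <= 1
        # joint mode on the same data agrees on the amplitude scale
        res_j = cosinor_test(g, y, t, mode="joint")
        assert res_j.amplitude == pytest.approx(res.amplitude, rel=0.5)

    def test_joint_chi2_exceeds_each_single_z2_on_balanced_design(self, rng):
        # with a full-day uniform window sin and cos interactions are nearly
        # orthogonal, so the 2-df statistic dominates each 1-df z^2
        n = 4000
        t = (np.arange(n) + 0.5) / n  # balanced time grid
        g = rng.binomial(2, 0.4, n).astype(float)
        y = g * (0.03 * np.sin(2 * np.pi * t)) + rng.normal(0, 0.3, n)
        res = cosinor_test(g, y, t, mode="joint")
        z_sin = res.beta_sin / res.se_sin
        z_cos = res.beta_cos / res.se_cos
        assert res.chi2_joint >= max(z_sin**2, z_cos**2) - 1e-6


class TestSignature:
    def test_mtnr1b_like_marginal_null_but_interaction_significant(self, mtnr1b_cohort):
        cfg, geno, samples = mtnr1b_cohort
        res = cosinor_test(
            geno.dosages[:, 0],
            samples["glucose_int"].to_numpy(),
            samples["t"].to_numpy(),
        )
        assert res.p_main > 0.01
        assert res.p_joint < 5e-8

    def test_morning_evening_effects_have_opposite_signs(self, mtnr1b_cohort):
        _, geno, samples = mtnr1b_cohort
        res = cosinor_test(
            geno.dosages[:, 0],
            samples["glucose_int"].to_numpy(),
            samples["t"].to_numpy(),
        )
        morning = effect_at_time(res, 9 / 24)
        evening = effect_at_time(res, 18 / 24)
        assert np.sign(morning) != np.sign(evening)

    def test_acrophase_recovered_near_generating_value(self, mtnr1b_cohort):
        cfg, geno, samples = mtnr1b_cohort
        res = cosinor_test(
            geno.dosages[:, 0],
            samples["glucose_int"].to_numpy(),
            samples["t"].to_numpy(),
        )
        gen_acro = acrophase_hours(cfg.beta_sin, cfg.beta_cos)
        delta = (res.acrophase_h - gen_acro + 12) % 24 - 12
        # daytime-only sampling leaves the interaction z's around 4-5 here,
        # so the peak time is only localised to a couple of hours
        assert abs(delta) < 3.0


class TestEffectAtTime:
    def test_zero_amplitude_constant(self):
        res = dg.CosinorResult(
            variant="v", n=10, beta_main=0.7, se_main=0.1, p_main=0.5,
            beta_sin=0.0, se_sin=0.1, beta_cos=0.0, se_cos=0.1,
            p_sin=1.0, p_cos=1.0, chi2_joint=0.0, p_joint=1.0,
            log10_p_joint=0.0, amplitude=0.0, acrophase_h=0.0,
        )
        np.testing.assert_allclose(effect_at_time(res, np.linspace(0, 0.99, 7)), 0.7)

    def test_three_four_five(self):
        assert np.hypot(3.0, 4.0) == pytest.approx(5.0)
        res = dg.CosinorResult(
            variant="v", n=10, beta_main=1.0, se_main=0.1, p_main=0.5,
            beta_sin=3.0, se_sin=0.1, beta_cos=4.0, se_cos=0.1,
            p_sin=0.0, p_cos=0.0, chi2_joint=1.0, p_joint=0.0,
            log10_p_joint=0.0, amplitude=5.0, acrophase_h=acrophase_hours(3.0, 4.0),
        )
        peak = effect_at_time(res, res.acrophase_h / 24.0)
        assert peak == pytest.approx(1.0 + 5.0, abs=1e-10)

    def test_pure_interaction_reverses_after_12h(self):
        res = dg.CosinorResult(
            variant="v", n=10, beta_main=0.0, se_main=0.1, p_main=0.5,
            beta_sin=0.02, se_sin=0.1, beta_cos=-0.01, se_cos=0.1,
            p_sin=0.0, p_cos=0.0, chi2_joint=1.0, p_joint=0.0,
            log10_p_joint=0.0, amplitude=np.hypot(0.02, 0.01), acrophase_h=0.0,
        )
        t = np.array([0.1, 0.3, 0.4])
        np.testing.assert_allclose(
            effect_at_time(res, t), -effect_at_time(res, (t + 0.5) % 1.0), atol=1e-12
        )


@pytest.fixture(scope="module")
def scan_cohort():
    cfg = dg.scenario("mtnr1b_like", n_samples=6000, seed=21, n_variants=41)
    # boost the causal amplitude so the small-n scan separates cleanly
    boost = 4.0
    cfg = dg.scenario(
        "mtnr1b_like", n_samples=6000, seed=21, n_variants=41,
        beta_sin=cfg.beta_sin * boost, beta_cos=cfg.beta_cos * boost,
    )
    geno, samples = dg.simulate_cohort(cfg)
    samples["glucose_int"] = dg.inverse_normal_transform(np.log(samples["glucose_raw"]))
    return cfg, geno, samples


class TestScan:
    def test_causal_variant_attains_minimum_p(self, scan_cohort):
        cfg, geno, samples = scan_cohort
        scan = CosinorScan().fit(geno, samples)
        best = scan.results_.loc[scan.results_["p_joint"].idxmin(), "variant"]
        assert best == geno.variants.loc[cfg.causal_variant, "id"]

    def test_duplicated_variant_gives_identical_rows(self, scan_cohort):
        _, geno, samples = scan_cohort
        dup = np.column_stack([geno.dosages[:, 0], geno.dosages[:, 0]])
        scan = CosinorScan().fit(dup, samples)
        a, b = scan.results_.iloc[0], scan.results_.iloc[1]
        for col in ("beta_sin", "beta_cos", "p_joint", "amplitude"):
            assert a[col] == b[col]

    def test_scan_is_deterministic(self, scan_cohort):
        _, geno, samples = scan_cohort
        r1 = CosinorScan().fit(geno, samples).results_
        r2 = CosinorScan().fit(geno, samples).results_
        assert r1.to_csv() == r2.to_csv()

    def test_monomorphic_variants_skipped_with_reason(self, scan_cohort):
        _, geno, samples = scan_cohort
        G = np.column_stack([geno.dosages[:, 0], np.zeros(len(samples))])
        scan = CosinorScan().fit(G, samples)
        assert len(scan.results_) == 1
        assert len(scan.skipped_) == 1 and "monomorphic" in scan.skipped_[0][1]

    def test_empty_scan_warns(self, scan_cohort):
        _, geno, samples = scan_cohort
        with pytest.warns(UserWarning, match="no testable"):
            scan = CosinorScan().fit(np.zeros((len(samples), 1)), samples)
        assert scan.results_.empty

    def test_sklearn_params_roundtrip(self):
        scan = CosinorScan(mode="separate", covariates=["sex"])
        params = scan.get_params()
        assert params["mode"] == "separate"
        scan.set_params(mode="joint")
        assert scan.mode == "joint"


class TestTimeShiftEquivariance:
    def test_six_hour_shift(self, mtnr1b_cohort):
        _, geno, samples = mtnr1b_cohort
        y = samples["glucose_int"].to_numpy()
        t = samples["t"].to_numpy()
        g = geno.dosages[:, 0]
        res0 = cosinor_test(g, y, t)
        res6 = cosinor_test(g, y, (t + 0.25) % 1.0)
        assert res6.amplitude == pytest.approx(res0.amplitude, rel=1e-6)
        assert res6.chi2_joint == pytest.approx(res0.chi2_joint, rel=1e-6)
        shift = (res6.acrophase_h - res0.acrophase_h) % 24.0
        assert shift == pytest.approx(6.0, abs=1e-6)


def test_null_joint_p_uniform():
    """2-df interaction p-values are uniform when no interaction was simulated."""
    rng = np.random.default_rng(12)
    ps = []
    for _ in range(400):
        n = 300
        t = rng.uniform(1 / 3, 5 / 6, n)
        g = rng.binomial(2, 0.3, n).astype(float)
        y = 0.1 * np.cos(2 * np.pi * t) + rng.normal(0, 1, n)
        ps.append(cosinor_test(g, y, t).p_joint)
    assert stats.kstest(ps, "uniform").statistic < 0.07
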