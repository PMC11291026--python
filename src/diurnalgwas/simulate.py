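"""Synthetic diurnal-biomarker cohorts.

Generates genotype/phenotype cohorts with the statistical structure the
time-of-day association analyses assume: Hardy-Weinberg genotypes at a
configured allele frequency, blood-draw clock times concentrated in a
daytime window, a population-level diurnal rhythm in log-glucose, and
genotype effects whose size varies sinusoidally over the day.  The
generative model is, deliberately, the same single-harmonic form the
cosinor scan fits:

    log glucose_i = mesor
                  + rhythm_amp * cos(2*pi*t_i - rhythm_phase)
                  + G_i * (beta_add + beta_sin*sin(2*pi*t_i)
                                    + beta_cos*cos(2*pi*t_i))
                  + covariate effects + N(0, noise_sd^2)

with t the fraction of the day elapsed at blood draw.  Raw glucose
(mmol/L) is the exponential.  Covariate contributions are mean-centred so
that exp(mesor + rhythm) is the exact population median trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GenotypeMatrix",
    "scenario",
    "simulate_genotypes",
    "simulate_draw_times",
    "simulate_phenotype",
    "simulate_cohort",
]

DAY_SECONDS = 86400

# ordered categorical sleep traits with population-style frequencies
SLEEP_TRAITS: dict[str, tuple[tuple[str, ...], tuple[float, ...]]] = {
    "chronotype": (
        ("definitely_morning", "more_morning", "more_evening", "definitely_evening"),
        (0.25, 0.35, 0.30, 0.10),
    ),
    "insomnia": (("never", "sometimes", "usually"), (0.25, 0.47, 0.28)),
    "sleep_duration": (("short", "normal", "long"), (0.25, 0.65, 0.10)),
    "napping": (("never", "sometimes", "usually"), (0.55, 0.40, 0.05)),
    "daytime_dozing": (("never", "sometimes", "often"), (0.75, 0.22, 0.03)),
    "ease_awakening": (
        ("not_easy", "fairly_easy", "very_easy"),
        (0.20, 0.50, 0.30),
    ),
}

N_PCS = 10
CENTRES = ("C1", "C2", "C3", "C4", "C5")
ARRAYS = ("axiom_full", "axiom_initial", "bileve")


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator.  Angles are radians; effects are on
    the log-glucose scale; times are seconds since midnight."""

    n_samples: int = 10_000
    n_variants: int = 1
    maf: float = 0.3
    draw_window: tuple = (8 * 3600, 20 * 3600)  # [start, end) seconds
    mesor: float = float(np.log(5.0))
    rhythm_amp: float = 0.03
    rhythm_phase: float = 2 * np.pi * 10 / 24  # population peak ~10:00
    beta_add: float = 0.0
    beta_sin: float = 0.0
    beta_cos: float = 0.0
    causal_variant: int = 0
    covariate_effects: dict = field(
        default_factory=lambda: {"sex": 0.03, "age": 0.002}
    )
    sleep_amp_factor: dict = field(default_factory=dict)
    noise_sd: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if not (np.isfinite(self.maf) and 0.0 < self.maf <= 0.5):
            raise ValueError(f"maf must lie in (0, 0.5], got {self.maf}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.draw_window
        if not (0 <= lo < hi <= DAY_SECONDS):
            raise ValueError(
                f"draw_window must satisfy 0 <= start < end <= 86400, got {self.draw_window}"
            )
        if self.n_samples < 1 or self.n_variants < 1:
            raise ValueError("n_samples and n_variants must be >= 1")

    def rng(self, stream: int) -> np.random.Generator:
        # independent, reproducible streams per generation stage
        return np.random.default_rng([int(self.seed) % (2**31), stream])


@dataclass
class GenotypeMatrix:
    """Dosage matrix (n_samples x n_variants, values in [0,2]) + metadata."""

    dosages: np.ndarray
    variants: pd.DataFrame  # id, chrom, pos, ref, alt, maf
    sample_ids: list

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def empirical_freq(self) -> np.ndarray:
        return self.dosages.mean(axis=0) / 2.0


def _sample_ids(n: int) -> list:
    return [f"S{i:06d}" for i in range(n)]


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Hard-call genotypes drawn under Hardy-Weinberg at the configured MAF."""
    rng = config.rng(1)
    n, m = config.n_samples, config.n_variants
    dos = rng.binomial(2, config.maf, size=(n, m)).astype(float)
    variants = pd.DataFrame(
        {
            "id": [f"var{j:04d}" for j in range(m)],
            "chrom": ["1"] * m,
            "pos": np.arange(1, m + 1) * 1000,
            "ref": ["A"] * m,
            "alt": ["G"] * m,
            "maf": [config.maf] * m,
        }
    )
    return GenotypeMatrix(dos, variants, _sample_ids(n))


def simulate_draw_times(config: SimulationConfig) -> np.ndarray:
    """Blood-draw times (seconds since midnight), uniform on the draw window."""
    lo, hi = config.draw_window
    rng = config.rng(2)
    return rng.uniform(lo, hi, size=config.n_samples)


def seconds_to_t(seconds) -> np.ndarray:
    """Fraction of the day elapsed, t = seconds / 86400, validated to [0,1)."""
    s = np.asarray(seconds, dtype=float)
    t = s / DAY_SECONDS
    if np.any((t < 0) | (t >= 1)):
        raise ValueError("draw times must lie in [0, 86400) seconds")
    return t


def genotype_effect(config: SimulationConfig, t: np.ndarray) -> np.ndarray:
    """Per-allele log-scale effect at day-fraction t."""
    return (
        config.beta_add
        + config.beta_sin * np.sin(2 * np.pi * t)
        + config.beta_cos * np.cos(2 * np.pi * t)
    )


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    draw_seconds: np.ndarray,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Sample table: glucose, draw time, fasting hours, covariates, sleep traits.

    The causal variant (``config.causal_variant``) carries the configured
    additive and sinusoidal per-allele effects; all other variants are null.
    """
    n = genotypes.n_samples
    if len(draw_seconds) != n:
        raise ValueError(
            f"genotypes have {n} samples but {len(draw_seconds)} draw times given"
        )
    t = seconds_to_t(draw_seconds)
    rng = config.rng(3)

    sex = rng.integers(0, 2, n)  # 0=F, 1=M
    age = rng.integers(40, 71, n).astype(float)
    centre = rng.choice(len(CENTRES), n)
    array = rng.choice(len(ARRAYS), n, p=(0.70, 0.20, 0.10))
    pcs = rng.standard_normal((n, N_PCS))
    fasting_hours = np.round(rng.gamma(shape=3.0, scale=1.5, size=n)).clip(0, 24)

    traits = {
        name: pd.Categorical.from_codes(
            rng.choice(len(levels), n, p=probs), categories=list(levels), ordered=True
        )
        for name, (levels, probs) in SLEEP_TRAITS.items()
    }

    g = genotypes.dosages[:, config.causal_variant]
    eff = genotype_effect(config, t)
    # optional sleep-trait modulation of the diurnal effect (power studies)
    if config.sleep_amp_factor:
        for trait_name, level_factors in config.sleep_amp_factor.items():
            codes = np.asarray(traits[trait_name].codes)
            levels = list(SLEEP_TRAITS[trait_name][0])
            factor = np.ones(n)
            for level, f in level_factors.items():
                factor[codes == levels.index(level)] = f
            eff = config.beta_add + factor * (eff - config.beta_add)

    cov_contrib = np.zeros(n)
    ce = config.covariate_effects or {}
    if "sex" in ce:
        cov_contrib += ce["sex"] * (sex - 0.5)
    if "age" in ce:
        cov_contrib += ce["age"] * (age - 55.0)
    for k, v in ce.items():
        if k.startswith("PC"):
            cov_contrib += v * pcs[:, int(k[2:]) - 1]

    log_glucose = (
        config.mesor
        + config.rhythm_amp * np.cos(2 * np.pi * t - config.rhythm_phase)
        + g * eff
        + cov_contrib
        + rng.normal(0.0, config.noise_sd, n)
    )

    table = pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids,
            "glucose_raw": np.exp(log_glucose),
            "draw_time": draw_seconds,
            "t": t,
            "fasting_hours": fasting_hours,
            "sex": np.where(sex == 1, "M", "F"),
            "age": age,
            "centre": [CENTRES[i] for i in centre],
            "array": [ARRAYS[i] for i in array],
        }
    )
    for j in range(N_PCS):
        table[f"PC{j + 1}"] = pcs[:, j]
    for name, values in traits.items():
        table[name] = values
    return table


def simulate_cohort(config: SimulationConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Genotypes + sample table in one call (single seed, bit-reproducible)."""
    geno = simulate_genotypes(config)
    times = simulate_draw_times(config)
    samples = simulate_phenotype(geno, times, config)
    return geno, samples


# ---------------------------------------------------------------------------
# scenario presets


def _amp_for_raw_morning_diff(
    target_mmol: float,
    mesor: float,
    rhythm_amp: float,
    rhythm_phase: float,
    effect_acro_t: float,
    at_t: float = 9.0 / 24.0,
) -> float:
    """Per-allele sinusoidal amplitude giving a target raw-scale homozygote
    (G=2 vs G=0) glucose difference at clock time ``at_t``."""
    base_log = mesor + rhythm_amp * np.cos(2 * np.pi * at_t - rhythm_phase)
    c = np.cos(2 * np.pi * (at_t - effect_acro_t))
    if abs(c) < 1e-12:
        raise ValueError("effect is zero at the calibration time")
    return float(np.log1p(target_mmol / np.exp(base_log)) / (2.0 * c))


def scenario(name: str, n_samples: int = 10_000, seed: int = 0, **overrides) -> SimulationConfig:
    """Named study conditions.

    ``"null"``
        No genotype effect; daytime draw window.
    ``"mtnr1b_like"``
        No time-constant effect; per-allele effect peaks at 08:00 (so it
        integrates to ~0 over the 08:00-20:00 draw window, reproducing the
        marginal-GWAS-null / diurnal-test-significant signature) with
        amplitude sized so homozygote carriers differ by 0.05 mmol/L at
        09:00; residual noise 0.05 log units.
    ``"constant_effect"``
        Time-constant per-allele effect 0.01 log units, no diurnal term.
    ``"variance_calibration"``
        Full-day draw window, no genotype or covariate effects; population
        rhythm amplitude set by the closed form amp = noise_sd * sqrt(2)/3,
        so the rhythm explains 10% of total variance (amp^2/2 over
        amp^2/2 + noise_sd^2).
    """
    base = dict(n_samples=n_samples, seed=seed)
    if name == "null":
        cfg = SimulationConfig(**base)
    elif name == "mtnr1b_like":
        acro_t = 8.0 / 24.0
        mesor = float(np.log(5.0))
        rhythm_amp, rhythm_phase = 0.03, 2 * np.pi * 10 / 24
        a = _amp_for_raw_morning_diff(0.05, mesor, rhythm_amp, rhythm_phase, acro_t)
        cfg = SimulationConfig(
            maf=0.3,
            mesor=mesor,
            rhythm_amp=rhythm_amp,
            rhythm_phase=rhythm_phase,
            beta_add=0.0,
            beta_sin=a * np.sin(2 * np.pi * acro_t),
            beta_cos=a * np.cos(2 * np.pi * acro_t),
            noise_sd=0.05,
            **base,
        )
    elif name == "constant_effect":
        cfg = SimulationConfig(beta_add=0.01, **base)
    elif name == "variance_calibration":
        noise_sd = 0.10
        cfg = SimulationConfig(
            draw_window=(0, DAY_SECONDS),
            rhythm_amp=noise_sd * np.sqrt(2.0) / 3.0,
            covariate_effects={},
            noise_sd=noise_sd,
            **base,
        )
    else:
        raise ValueError(f"unknown scenario {name!r}")
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg
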