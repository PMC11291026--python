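"""Morning/evening stratified contrasts, sleep-trait interaction models, and
variance explained by time of day.

The stratified design mirrors how a diurnal genetic effect is interrogated
when the full time axis is too thin: samples drawn before a morning cutoff
(default 11:00) and after an evening cutoff (default 17:00) — optionally
restricted to participants fasting at least 6/8/12 hours — are analysed
independently, and a sign flip of the per-allele effect between the two
windows is the qualitative fingerprint of a diurnal variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .linmod import (
    NotTestableError,
    encode_covariates,
    fit_ols,
    joint_chi2,
    wald_test,
)

__all__ = [
    "StrataSpec",
    "ContrastResult",
    "stratify",
    "window_contrast",
    "sleep_interaction_test",
    "stratified_effect_by_trait",
    "variance_explained_by_time",
]


@dataclass(frozen=True)
class StrataSpec:
    """Morning/evening windows plus an optional minimum fasting duration.

    ``fasting_min_hours`` is an "at least" threshold (None disables the
    fasting filter).  Samples between the two windows are excluded by
    design.
    """

    fasting_min_hours: float | None = None
    morning_end: float = 11.0  # clock hours
    evening_start: float = 17.0

    def __post_init__(self):
        if self.morning_end >= self.evening_start:
            raise ValueError("morning window must end before the evening window starts")
        if self.fasting_min_hours is not None and self.fasting_min_hours < 0:
            raise ValueError("fasting threshold must be >= 0")


@dataclass
class ContrastResult:
    variant: str
    stratum: str
    n: int
    beta: float
    se: float
    p: float


def stratify(samples: pd.DataFrame, spec: StrataSpec, time_col: str = "draw_time"):
    """Boolean masks for the morning and evening strata.

    Returns ``(masks, n_excluded)`` with ``masks = {"morning": ..., "evening": ...}``.
    """
    hours = samples[time_col].to_numpy(dtype=float) / 3600.0
    keep = np.ones(len(samples), dtype=bool)
    if spec.fasting_min_hours is not None:
        keep &= samples["fasting_hours"].to_numpy(dtype=float) >= spec.fasting_min_hours
    masks = {
        "morning": keep & (hours < spec.morning_end),
        "evening": keep & (hours >= spec.evening_start),
    }
    n_excluded = int(len(samples) - masks["morning"].sum() - masks["evening"].sum())
    return masks, n_excluded


def _stratum_fit(G, y, cov, mask, variant, stratum, min_n):
    n = int(mask.sum())
    if n < min_n or np.std(G[mask]) == 0:
        return None
    cols = {"const": np.ones(n)}
    if cov is not None:
        for c in cov.columns:
            cols[c] = cov[c].to_numpy(dtype=float)[mask]
    cols["G"] = G[mask]
    fit = fit_ols(y[mask], pd.DataFrame(cols))
    _, p = wald_test(fit, "G")
    return ContrastResult(
        variant=variant,
        stratum=stratum,
        n=fit.n,
        beta=float(fit.params["G"]),
        se=float(fit.bse["G"]),
        p=float(p),
    )


def window_contrast(
    G,
    samples: pd.DataFrame,
    spec: StrataSpec = StrataSpec(),
    covariates=None,
    phenotype_col: str = "glucose_adj",
    variant: str = "variant",
    min_n: int = 50,
):
    """Independent morning and evening association fits for one variant.

    Returns ``(results, opposite_sign)`` where ``results`` maps stratum name
    to :class:`ContrastResult` (missing if below ``min_n``) and
    ``opposite_sign`` is True iff both windows fitted and the effect signs
    differ (None when a window is missing).
    """
    G = np.asarray(G, dtype=float)
    y = samples[phenotype_col].to_numpy(dtype=float)
    cov = encode_covariates(samples, covariates)
    cov = cov if cov.shape[1] else None
    masks, _ = stratify(samples, spec)
    results = {}
    for name, mask in masks.items():
        label = name if spec.fasting_min_hours is None else f"{name}_fast{spec.fasting_min_hours:g}h"
        res = _stratum_fit(G, y, cov, mask, variant, label, min_n)
        if res is not None:
            results[name] = res
    if len(results) == 2:
        flag = bool(np.sign(results["morning"].beta) != np.sign(results["evening"].beta))
    else:
        flag = None
    return results, flag


def sleep_interaction_test(
    G,
    samples: pd.DataFrame,
    trait: str,
    covariates=None,
    phenotype_col: str = "glucose_adj",
    window_mask=None,
):
    """Genotype-by-sleep-trait interaction model within an (optional) window.

    Fits y ~ covariates + trait levels + G + G x trait levels and reports a
    joint chi-square over the interaction columns plus the trait main-effect
    fit.  Trait levels enter as factor indicators (first level reference).

    Returns a dict: chi2, df, p_interaction, trait main-effect frame, fit.
    """
    G = np.asarray(G, dtype=float)
    if window_mask is None:
        window_mask = np.ones(len(samples), dtype=bool)
    window_mask = np.asarray(window_mask, dtype=bool)
    sub = samples.loc[window_mask]
    g = G[window_mask]
    y = sub[phenotype_col].to_numpy(dtype=float)

    trait_col = sub[trait]
    observed = pd.Categorical(trait_col)
    levels = [lv for lv in observed.categories if (observed == lv).sum() > 0]
    if len(levels) < 2:
        raise NotTestableError(f"trait {trait!r} has fewer than 2 populated levels")
    dummies = pd.get_dummies(observed, prefix=trait, drop_first=True, dtype=float)
    dummies.index = sub.index
    dummies = dummies.loc[:, dummies.sum(axis=0) > 0]

    cov = encode_covariates(sub, covariates)
    cols = {"const": np.ones(len(sub))}
    for c in cov.columns:
        cols[c] = cov[c].to_numpy(dtype=float)
    for c in dummies.columns:
        cols[c] = dummies[c].to_numpy(dtype=float)
    cols["G"] = g
    inter_names = []
    for c in dummies.columns:
        name = f"G:{c}"
        cols[name] = g * dummies[c].to_numpy(dtype=float)
        inter_names.append(name)

    fit = fit_ols(y, pd.DataFrame(cols))
    testable = [n for n in inter_names if n in fit.params.index]
    if not testable:
        raise NotTestableError(f"all G x {trait} interaction columns dropped")
    chi2, df, p_int = joint_chi2(fit, testable)

    main = pd.DataFrame(
        {
            "term": list(dummies.columns),
            "beta": [fit.params.get(c, np.nan) for c in dummies.columns],
            "se": [fit.bse.get(c, np.nan) for c in dummies.columns],
        }
    )
    return {
        "chi2": chi2,
        "df": df,
        "p_interaction": p_int,
        "trait_main": main,
        "fit": fit,
    }


def stratified_effect_by_trait(
    G,
    samples: pd.DataFrame,
    trait: str,
    spec: StrataSpec = StrataSpec(),
    covariates=None,
    phenotype_col: str = "glucose_adj",
    min_n: int = 50,
) -> pd.DataFrame:
    """Morning/evening contrasts within each level of an ordered trait.

    Levels (or windows) below ``min_n`` are skipped; one row per fitted
    trait-level x window combination.
    """
    rows = []
    levels = pd.Categorical(samples[trait]).categories
    for level in levels:
        level_mask = (samples[trait] == level).to_numpy()
        if level_mask.sum() < min_n:
            continue
        sub = samples.loc[level_mask]
        res, flag = window_contrast(
            np.asarray(G, dtype=float)[level_mask],
            sub,
            spec=spec,
            covariates=covariates,
            phenotype_col=phenotype_col,
            min_n=min_n,
        )
        for window, r in res.items():
            rows.append(
                {
                    "trait_level": level,
                    "window": window,
                    "n": r.n,
                    "beta": r.beta,
                    "se": r.se,
                    "p": r.p,
                    "opposite_sign": flag,
                }
            )
    return pd.DataFrame(rows)


def variance_explained_by_time(
    y,
    draw_seconds,
    fasting_hours=None,
    fasting_min: float = 8.0,
    n_bins: int = 24,
) -> dict:
    """R^2 of an hourly time-of-day factor for a biomarker.

    Regresses ``y`` on a ``n_bins``-level clock-hour factor and reports the
    coefficient of determination for all samples and, when fasting durations
    are given, for the fasting subset (>= ``fasting_min`` hours).
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(draw_seconds, dtype=float)
    if y.size < 100:
        raise ValueError("variance_explained_by_time requires n >= 100")
    if np.std(y) == 0:
        raise ValueError("phenotype is degenerate (zero variance)")

    def r2(mask):
        yy, ss = y[mask], s[mask]
        codes = np.minimum((ss / 86400 * n_bins).astype(int), n_bins - 1)
        dummies = pd.get_dummies(codes, drop_first=True, dtype=float)
        X = pd.concat(
            [pd.DataFrame({"const": np.ones(len(yy))}, index=dummies.index), dummies],
            axis=1,
        )
        fit = fit_ols(yy, X)
        tss = float(np.sum((yy - yy.mean()) ** 2))
        return 1.0 - fit.rss / tss

    out = {"r2_all": r2(np.ones(y.size, dtype=bool)), "n_all": int(y.size)}
    if fasting_hours is not None:
        fmask = np.asarray(fasting_hours, dtype=float) >= fasting_min
        if fmask.sum() >= 100:
            out["r2_fasting"] = r2(fmask)
            out["n_fasting"] = int(fmask.sum())
    return out
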