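"""Time-binned association, fixed-effect meta-analysis, and cross-bin
heterogeneity testing.

Samples are split into clock-time windows of blood draw; the variant is
tested by plain linear regression within each window independently; the
per-window estimates are pooled by inverse-variance fixed-effect
meta-analysis; and Cochran's Q asks whether the window-specific effects are
consistent with a single shared effect.  A variant whose effect reverses
sign over the day is (near-)null marginally and in the meta-analysis, but
lights up in Q — the heterogeneity test is therefore the model-free
companion to the cosinor interaction scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .linmod import NotTestableError, encode_covariates, fit_ols, wald_test
from .simulate import DAY_SECONDS, GenotypeMatrix

__all__ = [
    "TimeBinning",
    "BINNING_PRESETS",
    "assign_bins",
    "per_bin_assoc",
    "fixed_effect_meta",
    "cochran_q",
    "i_squared",
    "windowed_scan",
    "WindowedScan",
]


@dataclass(frozen=True)
class TimeBinning:
    """Ordered, non-overlapping half-open clock-time bins [start, end)."""

    edges: tuple  # seconds since midnight, strictly increasing
    name: str = "custom"

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=float)
        if e.size < 2:
            raise ValueError("binning needs at least two edges")
        if np.any(np.diff(e) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if e[0] < 0 or e[-1] > DAY_SECONDS:
            raise ValueError("bin edges must lie within [0, 86400]")

    @classmethod
    def from_hours(cls, hours, name: str = "custom") -> "TimeBinning":
        return cls(tuple(float(h) * 3600 for h in hours), name)

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def labels(self) -> list:
        def hh(s):
            return f"{int(s // 3600):02d}:{int(s % 3600 // 60):02d}"

        return [
            f"[{hh(a)},{hh(b)})" for a, b in zip(self.edges[:-1], self.edges[1:])
        ]


BINNING_PRESETS = {
    # six 2-hour windows over the assessment-centre day
    "paper6": TimeBinning.from_hours(range(8, 21, 2), "paper6"),
    # one-hour windows 09:00-19:00
    "hourly": TimeBinning.from_hours(range(9, 20), "hourly"),
    # 24 hourly groups (clinical-registry style, round-the-clock draws)
    "estbb24": TimeBinning.from_hours(range(0, 25), "estbb24"),
}


def get_binning(binning) -> TimeBinning:
    if isinstance(binning, TimeBinning):
        return binning
    try:
        return BINNING_PRESETS[binning]
    except KeyError:
        raise ValueError(
            f"unknown binning {binning!r}; presets: {sorted(BINNING_PRESETS)}"
        ) from None


def assign_bins(draw_seconds, binning) -> np.ndarray:
    """Bin index per sample (half-open [start,end)); -1 = outside all bins."""
    binning = get_binning(binning)
    s = np.asarray(draw_seconds, dtype=float)
    idx = np.searchsorted(np.asarray(binning.edges), s, side="right") - 1
    idx[(s < binning.edges[0]) | (s >= binning.edges[-1])] = -1
    return idx.astype(int)


def per_bin_assoc(
    G,
    y,
    covariates: pd.DataFrame | None,
    bins: np.ndarray,
    n_bins: int,
    min_bin_n: int = 50,
) -> list[dict]:
    """Independent OLS of y on G (+ covariates) within each time bin.

    A bin is "unfit" when its sample count is below ``max(min_bin_n,
    n_columns + 11)`` or the variant is monomorphic inside it.
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    out = []
    for k in range(n_bins):
        m = bins == k
        n_k = int(m.sum())
        row = {"bin": k, "n": n_k, "beta": np.nan, "se": np.nan, "p": np.nan, "fit": False}
        cov_k = covariates.loc[m] if covariates is not None else None
        n_cols = 2 + (cov_k.shape[1] if cov_k is not None else 0)
        guard = max(min_bin_n, n_cols + 11)
        if n_k >= guard and np.std(G[m]) > 0:
            cols = {"const": np.ones(n_k)}
            if cov_k is not None:
                for c in cov_k.columns:
                    cols[c] = cov_k[c].to_numpy(dtype=float)
            cols["G"] = G[m]
            try:
                fit = fit_ols(y[m], pd.DataFrame(cols))
                _, p = wald_test(fit, "G")
            except (ValueError, NotTestableError):
                out.append(row)
                continue
            row.update(
                beta=float(fit.params["G"]), se=float(fit.bse["G"]), p=float(p), fit=True
            )
        out.append(row)
    if not any(r["fit"] for r in out):
        raise ValueError("no time bin passed the minimum-n guard")
    return out


def fixed_effect_meta(betas, ses) -> tuple[float, float, float]:
    """Inverse-variance fixed-effect pooling.  Returns (beta, se, p)."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size < 1:
        raise ValueError("meta-analysis needs at least one estimate")
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("standard errors must be positive and finite")
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return beta, se, p


def cochran_q(betas, ses) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity test across strata.

    Q = sum_k w_k (b_k - b_meta)^2, w_k = 1/se_k^2; p from chi-square with
    df = k - 1.  Raises :class:`NotTestableError` with fewer than 2 strata.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size < 2:
        raise NotTestableError("heterogeneity needs >= 2 fitted strata")
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("standard errors must be positive and finite")
    w = 1.0 / s**2
    b_meta = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - b_meta) ** 2))
    df = int(b.size - 1)
    p = float(stats.chi2.sf(q, df))
    return q, df, p


def i_squared(q: float, df: int) -> float:
    """I^2 = max(0, (Q - df)/Q): fraction of variation beyond sampling error."""
    if q <= 0:
        return 0.0
    return float(max(0.0, (q - df) / q))


class WindowedScan(BaseEstimator):
    """Per-variant time-binned association with meta-analysis and Cochran's Q.

    Parameters
    ----------
    binning : str | TimeBinning
        Preset name ("paper6", "hourly", "estbb24") or explicit binning.
    covariates : list[str] | None
    phenotype_col, time_col : str
        ``time_col`` must hold draw time in seconds since midnight.
    min_bin_n : int
        Minimum samples per fitted bin.
    sig_threshold : float
        Flag threshold for the heterogeneity p-value; a Bonferroni-across-
        bins flag (threshold / n_bins) is reported alongside.

    Attributes
    ----------
    results_ : pd.DataFrame   wide, one row per variant (meta + Q + I^2)
    long_ : pd.DataFrame      one row per variant x bin
    """

    def __init__(
        self,
        binning="paper6",
        covariates=None,
        phenotype_col: str = "glucose_int",
        time_col: str = "draw_time",
        min_bin_n: int = 50,
        sig_threshold: float = 5e-8,
    ):
        self.binning = binning
        self.covariates = covariates
        self.phenotype_col = phenotype_col
        self.time_col = time_col
        self.min_bin_n = min_bin_n
        self.sig_threshold = sig_threshold

    def fit(self, genotypes, samples: pd.DataFrame, y=None):
        binning = get_binning(self.binning)
        if isinstance(genotypes, GenotypeMatrix):
            dosages, ids = genotypes.dosages, list(genotypes.variants["id"])
        else:
            dosages = np.atleast_2d(np.asarray(genotypes, dtype=float))
            if dosages.shape[0] != len(samples):
                dosages = dosages.T
            ids = [f"var{j:04d}" for j in range(dosages.shape[1])]
        yv = samples[self.phenotype_col].to_numpy(dtype=float)
        bins = assign_bins(samples[self.time_col].to_numpy(dtype=float), binning)
        self.n_unassigned_ = int((bins == -1).sum())
        cov = encode_covariates(samples, self.covariates)
        cov = cov if cov.shape[1] else None
        labels = binning.labels

        wide_rows, long_rows = [], []
        for j, vid in enumerate(ids):
            g = dosages[:, j]
            try:
                per_bin = per_bin_assoc(
                    g, yv, cov, bins, binning.n_bins, self.min_bin_n
                )
            except ValueError as exc:
                warnings.warn(f"variant {vid}: {exc}", UserWarning)
                continue
            for r in per_bin:
                long_rows.append({"variant": vid, "label": labels[r["bin"]], **r})
            fitted = [r for r in per_bin if r["fit"]]
            b = [r["beta"] for r in fitted]
            s = [r["se"] for r in fitted]
            meta_b, meta_se, meta_p = fixed_effect_meta(b, s)
            if len(fitted) >= 2:
                q, df, p_het = cochran_q(b, s)
                i2 = i_squared(q, df)
            else:
                q, df, p_het, i2 = np.nan, 0, np.nan, np.nan
            row = {
                "variant": vid,
                "n_bins_fit": len(fitted),
                "meta_beta": meta_b,
                "meta_se": meta_se,
                "meta_p": meta_p,
                "Q": q,
                "df": df,
                "p_het": p_het,
                "i2": i2,
                "sig_het": bool(p_het < self.sig_threshold) if np.isfinite(p_het) else False,
                "sig_het_bonf_bins": bool(p_het < self.sig_threshold / binning.n_bins)
                if np.isfinite(p_het)
                else False,
            }
            for r in per_bin:
                lab = labels[r["bin"]]
                row[f"beta_{lab}"] = r["beta"]
                row[f"se_{lab}"] = r["se"]
                row[f"p_{lab}"] = r["p"]
                row[f"n_{lab}"] = r["n"]
            wide_rows.append(row)
        self.results_ = pd.DataFrame(wide_rows)
        self.long_ = pd.DataFrame(long_rows)
        self.binning_ = binning
        return self


def windowed_scan(
    genotypes,
    samples: pd.DataFrame,
    covariates=None,
    binning="paper6",
    phenotype_col: str = "glucose_int",
    min_bin_n: int = 50,
) -> pd.DataFrame:
    """Functional wrapper over :class:`WindowedScan` (wide results)."""
    scan = WindowedScan(
        binning=binning,
        covariates=covariates,
        phenotype_col=phenotype_col,
        min_bin_n=min_bin_n,
    )
    return scan.fit(genotypes, samples).results_
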