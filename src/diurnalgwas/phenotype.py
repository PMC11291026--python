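"""Biomarker phenotype derivation: log transform, quantile-binned covariate
factors, linear-model residualization, and rank-based inverse-normal transform.

The procedure mirrors how large biobank biomarker GWAS prepare a quantitative
trait: the raw measurement (e.g. serum glucose in mmol/L) is log-transformed,
technical and sociodemographic covariates — many of them entered as
quantile-binned factors and pairwise factor interactions — are removed by one
large ordinary-least-squares regression, and the residuals are rank-mapped to
normal quantiles (Blom offset) to give a unit-variance, outlier-robust
phenotype for association testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .linmod import FitResult, fit_ols

__all__ = [
    "CovariateSpec",
    "quantile_bin",
    "build_design",
    "residualize",
    "inverse_normal_transform",
    "PhenotypeAdjuster",
]


@dataclass
class CovariateSpec:
    """Declarative description of one covariate entering the residualization.

    kind:
        ``"categorical"``  — one-hot encoded, first (sorted) level dropped;
        ``"continuous"``   — entered as-is;
        ``"quantile_bin"`` — continuous column cut into ``n_bins``
        empirical-quantile factors first, then one-hot encoded.
    interactions:
        names of other covariates whose encoded columns are multiplied with
        this covariate's encoded columns (e.g. a sex-by-age-band indicator).
    """

    name: str
    kind: str = "categorical"
    n_bins: int = 20
    interactions: list = field(default_factory=list)

    def __post_init__(self):
        if self.kind not in ("categorical", "continuous", "quantile_bin"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "quantile_bin" and self.n_bins < 2:
            raise ValueError("quantile_bin requires n_bins >= 2")


def quantile_bin(values, n_bins: int) -> np.ndarray:
    """Cut a continuous vector into empirical-quantile bins.

    Returns integer codes 0..k-1.  Bins are rank-based: under no ties the bin
    sizes differ by at most one; tied values share an average rank and hence
    land deterministically in a single bin.  If ties (or too few distinct
    values) leave fewer than ``n_bins`` populated bins, codes are compacted
    and a warning is emitted.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("quantile_bin requires finite values")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    n = v.size
    ranks = stats.rankdata(v, method="average")  # 1..n
    codes = np.minimum((np.ceil(ranks / n * n_bins) - 1).astype(int), n_bins - 1)
    codes = np.maximum(codes, 0)
    used = np.unique(codes)
    if used.size < n_bins:
        warnings.warn(
            f"quantile_bin: only {used.size} of {n_bins} bins populated "
            "(ties or few distinct values); bins compacted",
            UserWarning,
            stacklevel=2,
        )
        remap = {c: i for i, c in enumerate(used)}
        codes = np.array([remap[c] for c in codes])
    return codes


def _encode_categorical(col: pd.Series, name: str) -> pd.DataFrame:
    """One-hot encode with the first sorted level as reference (dropped)."""
    cat = pd.Categorical(col)
    if len(cat.categories) < 1:
        raise ValueError(f"covariate {name!r} has no observed levels")
    dummies = pd.get_dummies(cat, prefix=name, drop_first=True, dtype=float)
    dummies.index = col.index
    return dummies


def build_design(
    samples: pd.DataFrame,
    spec: list,
    add_intercept: bool = True,
) -> tuple[pd.DataFrame, list]:
    """Assemble the residualization design matrix from covariate specs.

    Returns ``(design, dropped)`` where ``dropped`` lists collinear columns
    removed to reach full column rank.  Missing covariate columns raise a
    ``KeyError``; an all-missing covariate raises ``ValueError``.
    """
    blocks: dict[str, pd.DataFrame] = {}
    for cs in spec:
        if cs.name not in samples.columns:
            raise KeyError(f"covariate column {cs.name!r} missing from sample table")
        col = samples[cs.name]
        if col.isna().all():
            raise ValueError(f"covariate column {cs.name!r} is entirely missing")
        if cs.kind == "continuous":
            enc = pd.DataFrame({cs.name: pd.to_numeric(col)}, index=samples.index)
        elif cs.kind == "categorical":
            enc = _encode_categorical(col, cs.name)
        else:  # quantile_bin
            codes = quantile_bin(pd.to_numeric(col).to_numpy(), cs.n_bins)
            enc = _encode_categorical(
                pd.Series(codes, index=samples.index), f"{cs.name}_q{cs.n_bins}"
            )
        blocks[cs.name] = enc

    parts = []
    if add_intercept:
        parts.append(pd.DataFrame({"const": np.ones(len(samples))}, index=samples.index))
    parts.extend(blocks.values())

    # pairwise products of already-encoded blocks
    for cs in spec:
        for other in cs.interactions:
            if other not in blocks:
                raise KeyError(
                    f"interaction partner {other!r} of {cs.name!r} not in spec"
                )
            left, right = blocks[cs.name], blocks[other]
            prod = {}
            for lc in left.columns:
                for rc in right.columns:
                    prod[f"{lc}:{rc}"] = left[lc].to_numpy() * right[rc].to_numpy()
            parts.append(pd.DataFrame(prod, index=samples.index))

    design = pd.concat(parts, axis=1)
    from .linmod import drop_collinear

    design, dropped = drop_collinear(design)
    return design, dropped


def residualize(y, design: pd.DataFrame) -> tuple[np.ndarray, FitResult]:
    """OLS residuals of a (log-scale) biomarker on the covariate design."""
    fit = fit_ols(y, design)
    return fit.resid, fit


def inverse_normal_transform(values, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom offset.

    value_i = Phi^{-1}((rank_i - c) / (n - 2c + 1)), average ranks for ties.
    Non-finite entries propagate as NaN (excluded from ranking); their count
    is reported in a warning.
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    ok = np.isfinite(v)
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(
            f"inverse_normal_transform: excluded {n_bad} non-finite values",
            UserWarning,
            stacklevel=2,
        )
    n = int(ok.sum())
    if n < 2:
        raise ValueError("inverse_normal_transform requires >= 2 finite values")
    ranks = stats.rankdata(v[ok], method="average")
    out[ok] = stats.norm.ppf((ranks - c) / (n - 2.0 * c + 1.0))
    return out


class PhenotypeAdjuster(BaseEstimator, TransformerMixin):
    """Derive an adjusted biomarker phenotype for association testing.

    Pipeline: optional plausibility filter on the raw scale -> log transform
    -> OLS residualization on a declarative covariate design ->
    rank-based inverse-normal transform.

    Parameters
    ----------
    covariates : list[CovariateSpec] | None
        Covariate specification; ``None`` means intercept-only (the adjusted
        phenotype is then mean-centred log biomarker).
    log_transform : bool
        Log the raw values first (biomarkers are strictly positive).
    valid_range : tuple | None
        Raw-scale plausibility interval (lo, hi]; values outside are set to
        missing before adjustment.  Off (``None``) by default; clinical-
        registry style cohorts use e.g. ``(1, 15)`` for glucose in mmol/L.
    int_offset : float
        Rank offset c of the inverse-normal transform (Blom, 3/8).

    Attributes (after fit)
    ----------------------
    design_: pd.DataFrame          fitted design matrix
    fit_: FitResult                residualization fit (R^2, dropped columns)
    dropped_: list[str]            collinear design columns removed
    n_excluded_: int               samples excluded (range filter / missing)
    """

    def __init__(
        self,
        covariates=None,
        log_transform: bool = True,
        valid_range=None,
        int_offset: float = 3.0 / 8.0,
    ):
        self.covariates = covariates
        self.log_transform = log_transform
        self.valid_range = valid_range
        self.int_offset = int_offset

    def _prepare_y(self, samples: pd.DataFrame, value_col: str) -> np.ndarray:
        y = pd.to_numeric(samples[value_col]).to_numpy(dtype=float)
        if self.valid_range is not None:
            lo, hi = self.valid_range
            y = np.where((y > lo) & (y <= hi), y, np.nan)
        if self.log_transform:
            with np.errstate(invalid="ignore"):
                bad = ~(y > 0)
            y = np.where(bad, np.nan, y)
            y = np.log(y)
        return y

    def fit(self, samples: pd.DataFrame, y=None, value_col: str = "glucose_raw"):
        y_vec = self._prepare_y(samples, value_col)
        spec = self.covariates or []
        if spec:
            design, dropped = build_design(samples, spec)
        else:
            design = pd.DataFrame(
                {"const": np.ones(len(samples))}, index=samples.index
            )
            dropped = []
        self.design_ = design
        ok = np.isfinite(y_vec)
        self.n_excluded_ = int((~ok).sum())
        fit = fit_ols(y_vec, design)
        self.fit_ = fit
        self.dropped_ = dropped + fit.dropped
        self._value_col = value_col
        return self

    def transform(self, samples: pd.DataFrame) -> pd.DataFrame:
        """Return a copy of ``samples`` with ``*_adj`` and ``*_int`` columns."""
        y_vec = self._prepare_y(samples, self._value_col)
        design = self.design_.loc[:, self.fit_.params.index]
        pred = design.to_numpy(dtype=float) @ self.fit_.params.to_numpy()
        resid = y_vec - pred
        out = samples.copy()
        out[f"{self._value_col.replace('_raw', '')}_adj"] = resid
        out[f"{self._value_col.replace('_raw', '')}_int"] = inverse_normal_transform(
            resid, c=self.int_offset
        )
        return out

    def fit_transform(self, samples: pd.DataFrame, y=None, **fit_params):
        return self.fit(samples, **fit_params).transform(samples)
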