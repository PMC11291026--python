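"""Spline-by-genotype trajectories of the raw biomarker over clock time.

Unadjusted glucose (mmol/L) is modelled as a smooth function of draw time
with a natural cubic spline (knots at empirical quantiles of t), genotype
entered as a 3-class factor, and genotype-by-spline interaction columns
allowing each genotype class its own curve.  The diurnal-genotype test is
the nested-model F test of the interaction columns against a null in which
all classes share one curve and differ only by vertical offsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from patsy import build_design_matrices, dmatrix
from scipy import stats
from sklearn.base import BaseEstimator

from .linmod import encode_covariates, fit_ols

__all__ = [
    "spline_basis",
    "TrajectoryFit",
    "fit_genotype_trajectory",
    "TrajectoryModel",
]


def spline_basis(t, df: int):
    """Natural cubic spline basis (no intercept column) with quantile knots.

    Returns ``(basis, design_info)``; ``design_info`` re-evaluates the same
    basis on new points.  Requires df >= 3 and more distinct values than df.
    """
    t = np.asarray(t, dtype=float)
    if df < 3:
        raise ValueError("spline df must be >= 3")
    if np.unique(t).size <= df:
        raise ValueError(
            f"spline df={df} exceeds support ({np.unique(t).size} distinct values)"
        )
    mat = dmatrix("cr(x, df=%d) - 1" % df, {"x": t}, return_type="matrix")
    basis = np.asarray(mat)
    if np.linalg.matrix_rank(basis) < df:
        raise ValueError("spline basis is rank deficient on this support")
    return basis, mat.design_info


@dataclass
class TrajectoryFit:
    """Per-genotype fitted time curves plus the shared-curve interaction test."""

    f_stat: float
    df_num: int
    df_den: int
    p_interaction: float
    classes: list
    basis_df: int
    t_range: tuple
    # internals needed for prediction
    _design_info: object
    _fit_full: object
    _cov_means: dict
    _class_counts: dict
    merged: bool = False

    def describe_basis(self) -> str:
        return f"natural cubic spline, df={self.basis_df}, quantile knots on t in {self.t_range}"


def _trajectory_design(basis, g_codes, classes, cov: pd.DataFrame | None, interactions: bool):
    n, df = basis.shape
    cols = {"const": np.ones(n)}
    if cov is not None:
        for c in cov.columns:
            cols[c] = cov[c].to_numpy(dtype=float)
    for k in range(df):
        cols[f"s{k}"] = basis[:, k]
    for cls in classes[1:]:
        cols[f"g{cls}"] = (g_codes == cls).astype(float)
    if interactions:
        for cls in classes[1:]:
            ind = (g_codes == cls).astype(float)
            for k in range(df):
                cols[f"g{cls}:s{k}"] = ind * basis[:, k]
    return pd.DataFrame(cols)


def fit_genotype_trajectory(
    y_raw,
    t,
    g,
    covariates: pd.DataFrame | None = None,
    df: int = 5,
    min_class_n: int = 100,
) -> TrajectoryFit:
    """Fit per-genotype time curves and test genotype-dependent trajectories.

    Parameters
    ----------
    y_raw : raw biomarker (positive, mmol/L scale)
    t : day fraction in [0,1)
    g : hard-call genotype classes in {0,1,2} (dosages are rounded)
    covariates : numeric design columns or None
    df : spline degrees of freedom
    min_class_n : classes below this count are merged toward the
        heterozygote (dominance coding) with a warning; an error is raised
        if merging cannot produce two adequate classes.
    """
    y_raw = np.asarray(y_raw, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(y_raw <= 0):
        raise ValueError("raw biomarker values must be positive")
    g_codes = np.rint(np.asarray(g, dtype=float)).astype(int)
    if np.any((g_codes < 0) | (g_codes > 2)):
        raise ValueError("genotype classes must be 0, 1 or 2")

    counts = {c: int((g_codes == c).sum()) for c in (0, 1, 2)}
    merged = False
    if min(counts.values()) < min_class_n:
        # dominance merge: fold the rare homozygote into the heterozygote
        rare = min((c for c in (0, 2)), key=lambda c: counts[c])
        if counts[rare] < min_class_n:
            g_codes = np.where(g_codes == rare, 1, g_codes)
            merged = True
            warnings.warn(
                f"genotype class {rare} below min_class_n={min_class_n}; "
                "merged into heterozygotes (dominance coding)",
                UserWarning,
            )
        counts = {c: int((g_codes == c).sum()) for c in np.unique(g_codes)}
        if len(counts) < 2 or min(counts.values()) < min_class_n:
            raise ValueError(
                f"cannot form >= 2 genotype classes of n >= {min_class_n}: {counts}"
            )
    classes = sorted(np.unique(g_codes))

    basis, design_info = spline_basis(t, df)
    X_full = _trajectory_design(basis, g_codes, classes, covariates, True)
    X_null = _trajectory_design(basis, g_codes, classes, covariates, False)
    fit_full = fit_ols(y_raw, X_full)
    fit_null = fit_ols(y_raw, X_null)

    q = fit_null.df_resid - fit_full.df_resid
    f_stat = ((fit_null.rss - fit_full.rss) / q) / (fit_full.rss / fit_full.df_resid)
    p_int = float(stats.f.sf(f_stat, q, fit_full.df_resid))

    cov_means = (
        {c: float(covariates[c].mean()) for c in covariates.columns}
        if covariates is not None
        else {}
    )
    return TrajectoryFit(
        f_stat=float(f_stat),
        df_num=int(q),
        df_den=int(fit_full.df_resid),
        p_interaction=p_int,
        classes=[int(c) for c in classes],
        basis_df=df,
        t_range=(float(t.min()), float(t.max())),
        _design_info=design_info,
        _fit_full=fit_full,
        _cov_means=cov_means,
        _class_counts=counts,
        merged=merged,
    )


def predict_curves(fit: TrajectoryFit, grid_t) -> pd.DataFrame:
    """Per-class fitted curves with 95% pointwise bands at covariate means.

    ``grid_t`` (day fractions) must lie within the observed time support —
    spline extrapolation is refused.
    """
    grid_t = np.asarray(grid_t, dtype=float)
    lo, hi = fit.t_range
    if np.any(grid_t < lo) or np.any(grid_t > hi):
        raise ValueError(f"grid extends outside observed time support [{lo}, {hi}]")
    (basis,) = build_design_matrices([fit._design_info], {"x": grid_t})
    basis = np.asarray(basis)
    params = fit._fit_full.params
    cov = fit._fit_full.cov
    names = list(params.index)

    rows = []
    for cls in fit.classes:
        X = pd.DataFrame(0.0, index=range(len(grid_t)), columns=names)
        X["const"] = 1.0
        for cname, mean in fit._cov_means.items():
            if cname in X.columns:
                X[cname] = mean
        for k in range(fit.basis_df):
            if f"s{k}" in X.columns:
                X[f"s{k}"] = basis[:, k]
        if cls != fit.classes[0]:
            if f"g{cls}" in X.columns:
                X[f"g{cls}"] = 1.0
            for k in range(fit.basis_df):
                col = f"g{cls}:s{k}"
                if col in X.columns:
                    X[col] = basis[:, k]
        A = X.to_numpy(dtype=float)
        mean = A @ params.to_numpy()
        var = np.einsum("ij,jk,ik->i", A, cov.to_numpy(), A)
        se = np.sqrt(np.maximum(var, 0.0))
        rows.append(
            pd.DataFrame(
                {
                    "t": grid_t,
                    "time_h": grid_t * 24.0,
                    "g_class": cls,
                    "mean": mean,
                    "lo": mean - 1.96 * se,
                    "hi": mean + 1.96 * se,
                    "se": se,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


class TrajectoryModel(BaseEstimator):
    """Spline-by-genotype trajectory estimator for a single variant.

    Parameters
    ----------
    df : spline degrees of freedom (natural cubic, quantile knots)
    covariates : list[str] | None — sample-table columns to adjust for
    response_col, time_col : sample-table columns (raw biomarker, day fraction)
    min_class_n : minimum per-genotype-class sample count

    Attributes
    ----------
    fit_ : TrajectoryFit
    p_interaction_ : float
    """

    def __init__(
        self,
        df: int = 5,
        covariates=None,
        response_col: str = "glucose_raw",
        time_col: str = "t",
        min_class_n: int = 100,
    ):
        self.df = df
        self.covariates = covariates
        self.response_col = response_col
        self.time_col = time_col
        self.min_class_n = min_class_n

    def fit(self, g, samples: pd.DataFrame, y=None):
        cov = encode_covariates(samples, self.covariates)
        cov = cov if cov.shape[1] else None
        self.fit_ = fit_genotype_trajectory(
            samples[self.response_col].to_numpy(dtype=float),
            samples[self.time_col].to_numpy(dtype=float),
            np.asarray(g, dtype=float),
            covariates=cov,
            df=self.df,
            min_class_n=self.min_class_n,
        )
        self.p_interaction_ = self.fit_.p_interaction
        return self

    def predict(self, grid_t) -> pd.DataFrame:
        return predict_curves(self.fit_, grid_t)
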