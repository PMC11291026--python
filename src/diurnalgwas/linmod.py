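"""Per-variant linear-model engine: OLS fits, Wald tests, joint chi-square tests.

Every association scan in the package (cosinor, windowed, trajectory,
stratified) reduces to ordinary least squares on a dense design matrix
followed by Wald-type inference.  Model-based (homoskedastic) standard
errors are used throughout; at the simulated-cohort scale of this package,
with unrelated samples and Gaussian noise, this is the same test a
whole-genome-regression tool would report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "FitResult",
    "fit_ols",
    "wald_test",
    "joint_chi2",
    "NotTestableError",
]


class NotTestableError(ValueError):
    """Raised when a requested coefficient cannot be tested (dropped or missing)."""


@dataclass
class FitResult:
    """OLS fit summary for one model.

    Attributes
    ----------
    params : pd.Series
        Coefficient estimates, indexed by column name (retained columns only).
    bse : pd.Series
        Model-based standard errors.
    cov : pd.DataFrame
        Covariance matrix of the estimates.
    resid : np.ndarray
        Residual vector (same length as the rows actually used).
    sigma2 : float
        Residual variance estimate, RSS / (n - rank).
    n : int
        Number of rows used (complete cases).
    df_resid : int
        Residual degrees of freedom.
    dropped : list[str]
        Collinear columns removed to reach full rank.
    rss : float
        Residual sum of squares.
    """

    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    resid: np.ndarray
    sigma2: float
    n: int
    df_resid: int
    dropped: list = field(default_factory=list)
    rss: float = np.nan

    @property
    def zvalues(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        z = self.zvalues
        return pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=z.index)

    @property
    def r_squared(self) -> float:
        resid = self.resid
        tss = float(np.sum((self._y_centered) ** 2))
        if tss == 0:
            return 0.0
        return 1.0 - self.rss / tss

    # populated by fit_ols; kept out of the dataclass signature
    _y_centered: np.ndarray = field(default=None, repr=False)


def _as_design(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def drop_collinear(X: pd.DataFrame, tol: float = 1e-9) -> tuple[pd.DataFrame, list]:
    """Return a full-column-rank sub-design, dropping later columns first.

    Rank is detected by pivoted QR; among a collinear set the column that
    appears first in ``X`` is retained, so the intercept and main effects
    survive duplicated or aliased covariates.
    """
    A = X.to_numpy(dtype=float)
    if A.shape[1] == 0:
        return X, []
    # QR with column pivoting: R diagonal decays; rank = #|diag| above tol
    _, R, piv = linalg.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    scale = diag[0] if diag.size and diag[0] > 0 else 1.0
    rank = int(np.sum(diag > tol * scale))
    if rank == A.shape[1]:
        return X, []
    keep_piv = sorted(piv[:rank])
    # pivoting may favour a later duplicate column; prefer earliest columns
    # by greedily re-checking rank on the first-come ordering
    keep: list[int] = []
    for j in range(A.shape[1]):
        cols = keep + [j]
        sub = A[:, cols]
        if np.linalg.matrix_rank(sub, tol=tol * scale) == len(cols):
            keep.append(j)
        if len(keep) == rank:
            break
    dropped = [c for i, c in enumerate(X.columns) if i not in keep]
    return X.iloc[:, keep], dropped


def fit_ols(y, X, add_intercept: bool = False) -> FitResult:
    """Ordinary least squares of ``y`` on design ``X`` via SVD least squares.

    Rows with any non-finite value in ``y`` or ``X`` are excluded
    (complete-case).  Collinear columns are dropped (recorded in
    ``FitResult.dropped``) before fitting.

    Raises
    ------
    ValueError
        If the number of usable rows does not exceed the design rank.
    """
    X = _as_design(X).copy()
    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise ValueError(f"y has {len(y)} rows, design has {len(X)}")
    if add_intercept and "const" not in X.columns:
        X.insert(0, "const", 1.0)

    mask = np.isfinite(y) & np.isfinite(X.to_numpy(dtype=float)).all(axis=1)
    y = y[mask]
    X = X.loc[mask]

    X, dropped = drop_collinear(X)
    A = X.to_numpy(dtype=float)
    n, k = A.shape
    if n <= k:
        raise ValueError(f"insufficient data: n={n} rows for rank-{k} design")

    beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    rss = float(resid @ resid)
    df_resid = n - k
    sigma2 = rss / df_resid
    XtX_inv = np.linalg.inv(A.T @ A)
    cov = XtX_inv * sigma2
    bse = np.sqrt(np.diag(cov))

    cols = list(X.columns)
    fit = FitResult(
        params=pd.Series(beta, index=cols),
        bse=pd.Series(bse, index=cols),
        cov=pd.DataFrame(cov, index=cols, columns=cols),
        resid=resid,
        sigma2=sigma2,
        n=n,
        df_resid=df_resid,
        dropped=dropped,
        rss=rss,
    )
    fit._y_centered = y - y.mean()
    return fit


def wald_test(fit: FitResult, name: str) -> tuple[float, float]:
    """Two-sided Wald test of a single coefficient.

    Returns ``(z, p)``.  A coefficient that was dropped for collinearity
    (or never present) raises :class:`NotTestableError`.
    """
    if name in fit.dropped:
        raise NotTestableError(f"coefficient {name!r} was dropped as collinear")
    if name not in fit.params.index:
        raise NotTestableError(f"coefficient {name!r} not in model")
    se = fit.bse[name]
    if not np.isfinite(se) or se <= 0:
        raise NotTestableError(f"coefficient {name!r} has invalid SE {se}")
    z = fit.params[name] / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def joint_chi2(fit: FitResult, names: list) -> tuple[float, int, float]:
    """Joint Wald chi-square test that a named coefficient subvector is zero.

    chi2 = b' V^{-1} b with V the covariance submatrix of the named
    coefficients; p from the chi-square distribution with df = len(names).

    Returns ``(chi2, df, p)``.
    """
    names = list(names)
    missing = [m for m in names if m not in fit.params.index]
    if missing:
        raise NotTestableError(f"coefficients not retained in model: {missing}")
    b = fit.params[names].to_numpy()
    V = fit.cov.loc[names, names].to_numpy()
    try:
        sol = linalg.solve(V, b, assume_a="pos")
    except linalg.LinAlgError as exc:
        raise NotTestableError(
            f"singular covariance submatrix for {names}"
        ) from exc
    chi2 = float(b @ sol)
    if chi2 < 0:  # numerical noise on a PSD form
        chi2 = 0.0
    df = len(names)
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def encode_covariates(samples: pd.DataFrame, names) -> pd.DataFrame:
    """Numeric design columns for scan covariates.

    Numeric columns enter as-is; object/categorical columns are one-hot
    encoded with the first (sorted) level as reference.  No intercept.
    """
    parts = []
    for name in names or []:
        if name not in samples.columns:
            raise KeyError(f"covariate column {name!r} missing from sample table")
        col = samples[name]
        if pd.api.types.is_numeric_dtype(col):
            parts.append(col.astype(float).rename(name))
        else:
            dummies = pd.get_dummies(
                pd.Categorical(col), prefix=name, drop_first=True, dtype=float
            )
            dummies.index = samples.index
            parts.append(dummies)
    if not parts:
        return pd.DataFrame(index=samples.index)
    return pd.concat(parts, axis=1)


def log10_sf_chi2(chi2: float, df: int) -> float:
    """log10 upper-tail chi-square probability, safe against underflow."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.chi2.logsf(chi2, df) / np.log(10.0))
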