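"""Correlation-matrix PCA / factor analysis with varimax rotation,
plus KMO and Bartlett sampling-adequacy diagnostics.

Loadings are eigenvector_k * sqrt(lambda_k) of the correlation matrix;
percent variance per factor is 100 * lambda_k / n_variables and is
reported from the unrotated eigenvalues even when the displayed loadings
are varimax-rotated (the conventional presentation for varifactor
tables). Varimax is performed on Kaiser-normalized rows (each row of
the loading matrix divided by the square root of its communality) and
preserves communalities exactly, orthogonal rotations being row-norm
preserving.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class FactorLoadings:
    loadings: pd.DataFrame          # variables x retained factors
    eigenvalues: np.ndarray         # all eigenvalues, descending
    percent_variance: np.ndarray    # per retained factor, 100*lambda/p_vars
    cumulative_percent: np.ndarray
    communalities: pd.Series        # per variable, over retained factors
    rotated: bool = False
    notes: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class SuitabilityDiagnostics:
    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    n: int


def _correlation(matrix: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Correlation matrix after listwise deletion of incomplete rows."""
    complete = matrix.dropna(axis=0, how="any")
    if len(complete) < 3:
        raise ValueError("need at least 3 complete rows")
    stds = complete.std(ddof=1)
    zero = stds[stds == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance column(s): {zero}")
    return complete.corr(), len(complete)


def pca_fa(matrix: pd.DataFrame, retain="kaiser") -> FactorLoadings:
    """PCA on the correlation matrix of ``matrix`` (samples x variables).

    Columns are standardized internally (the correlation matrix is
    scale-free); rows with any missing value are dropped listwise.
    ``retain`` is "kaiser" (eigenvalue > 1) or an integer factor count.
    """
    corr, n = _correlation(matrix)
    p_vars = corr.shape[1]
    eigval, eigvec = np.linalg.eigh(corr.to_numpy())
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)

    if retain == "kaiser":
        k = max(int((eigval > 1.0).sum()), 1)
    else:
        k = int(retain)
        if not 1 <= k <= p_vars:
            raise ValueError(f"retain must be in 1..{p_vars}")
    load = eigvec[:, :k] * np.sqrt(eigval[:k])
    # deterministic sign: largest-|loading| entry of each factor positive
    for j in range(k):
        i = np.argmax(np.abs(load[:, j]))
        if load[i, j] < 0:
            load[:, j] = -load[:, j]
    cols = [f"VF{i + 1}" for i in range(k)]
    loadings = pd.DataFrame(load, index=corr.index, columns=cols)
    pct = percent_variance(eigval[:k], p_vars)
    return FactorLoadings(
        loadings=loadings,
        eigenvalues=eigval,
        percent_variance=pct,
        cumulative_percent=np.cumsum(pct),
        communalities=(loadings ** 2).sum(axis=1),
        rotated=False,
        notes=[f"n={n} complete rows, retain={retain!r}"],
    )


def percent_variance(eigenvalues, p_vars: int) -> np.ndarray:
    """Percent of total variance per factor: 100 * lambda / n_variables."""
    return 100.0 * np.asarray(eigenvalues, dtype=float) / p_vars


def varimax_rotate(fl: FactorLoadings, kaiser_normalize: bool = True,
                   tol: float = 1e-10, max_iter: int = 500) -> FactorLoadings:
    """Varimax rotation of retained loadings (Kaiser-normalized rows).

    Returns a new :class:`FactorLoadings` with rotated loadings, the
    same unrotated eigenvalues / percent-variance accounting, and
    communalities unchanged (orthogonality). A single factor is
    returned unchanged with a note.
    """
    L = fl.loadings.to_numpy().copy()
    p, k = L.shape
    if k < 2:
        out = _copy_with(fl, fl.loadings.copy(), rotated=False)
        out.notes.append("single factor: varimax is a no-op")
        return out
    h = np.sqrt((L ** 2).sum(axis=1))
    if kaiser_normalize:
        if np.any(h == 0):
            raise ValueError("zero communality row; cannot Kaiser-normalize")
        L = L / h[:, None]
    R = np.eye(k)
    var_old = _varimax_criterion(L)
    for _ in range(max_iter):
        B = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (B ** 3 - B @ np.diag((B ** 2).sum(axis=0)) / p))
        R = u @ vt
        var_new = _varimax_criterion(L @ R)
        if var_new - var_old < tol * max(var_old, 1.0):
            break
        var_old = var_new
    rot = L @ R
    if kaiser_normalize:
        rot = rot * h[:, None]
    for j in range(k):
        i = np.argmax(np.abs(rot[:, j]))
        if rot[i, j] < 0:
            rot[:, j] = -rot[:, j]
    rotated = pd.DataFrame(rot, index=fl.loadings.index,
                           columns=fl.loadings.columns)
    return _copy_with(fl, rotated, rotated=True)


def _copy_with(fl: FactorLoadings, loadings: pd.DataFrame,
               rotated: bool) -> FactorLoadings:
    return FactorLoadings(
        loadings=loadings,
        eigenvalues=fl.eigenvalues.copy(),
        percent_variance=fl.percent_variance.copy(),
        cumulative_percent=fl.cumulative_percent.copy(),
        communalities=(loadings ** 2).sum(axis=1),
        rotated=rotated,
        notes=list(fl.notes),
    )


def _varimax_criterion(L: np.ndarray) -> float:
    """Raw varimax criterion: sum over factors of column variance of L^2."""
    sq = L ** 2
    return float((sq ** 2).sum() - (sq.sum(axis=0) ** 2).sum() / L.shape[0])


def kmo(correlation: pd.DataFrame | np.ndarray) -> float:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    With S the inverse correlation matrix, the partial correlations are
    q_ij = -s_ij / sqrt(s_ii s_jj) and
    KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over i != j.
    """
    R = np.asarray(correlation, dtype=float)
    if R.shape[0] != R.shape[1] or not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric square")
    try:
        S = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular correlation matrix") from exc
    d = np.sqrt(np.diag(S))
    Q = -S / np.outer(d, d)
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = float((R[off] ** 2).sum())
    q2 = float((Q[off] ** 2).sum())
    if r2 + q2 < 1e-12:
        log.warning("kmo: near-identity correlation matrix; KMO ill-conditioned")
        return float("nan")
    return r2 / (r2 + q2)


def bartlett_sphericity(correlation: pd.DataFrame | np.ndarray,
                        n: int) -> tuple[float, int, float]:
    """Bartlett test of sphericity (H0: correlation matrix is identity).

    chi2 = -(n - 1 - (2p + 5)/6) * ln det R with df = p(p-1)/2.
    """
    R = np.asarray(correlation, dtype=float)
    p = R.shape[0]
    if n <= p:
        raise ValueError("need n > number of variables")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("correlation matrix must have positive determinant")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    return float(chi2), df, float(stats.chi2.sf(chi2, df))


def suitability(matrix: pd.DataFrame) -> SuitabilityDiagnostics:
    """KMO + Bartlett diagnostics of a samples x variables matrix."""
    corr, n = _correlation(matrix)
    chi2, df, p = bartlett_sphericity(corr, n)
    return SuitabilityDiagnostics(kmo=kmo(corr), bartlett_chi2=chi2,
                                  bartlett_df=df, bartlett_p=p, n=n)


def classify_loadings(fl: FactorLoadings,
                      strong: float = 0.70,
                      moderate: float = 0.50) -> pd.DataFrame:
    """Label each loading by absolute value: >0.70 strong, 0.5-0.7 moderate."""
    a = fl.loadings.abs()
    out = pd.DataFrame("none", index=a.index, columns=a.columns)
    out = out.mask(a >= moderate, "moderate").mask(a > strong, "strong")
    return out


def loadings_table(fl: FactorLoadings) -> pd.DataFrame:
    """Variables x factors table with eigenvalue/%/cumulative footer rows."""
    k = fl.loadings.shape[1]
    footer = pd.DataFrame(
        [fl.eigenvalues[:k], fl.percent_variance, fl.cumulative_percent],
        index=["Eigenvalues", "% of Variance", "Cumulative %"],
        columns=fl.loadings.columns,
    )
    return pd.concat([fl.loadings, footer])
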