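"""Positive matrix factorization receptor model.

Decomposes a non-negative samples x parameters concentration matrix X
into p source contributions G (samples x p) and source profiles F
(p x parameters), X ~ GF with G, F >= 0, by minimizing the
uncertainty-weighted objective

    Q = sum_ij [ (x_ij - sum_k g_ik f_kj) / u_ij ]^2 .

Cell uncertainties follow the standard receptor-model convention:
u = sqrt((EF * x)^2 + (0.5 * MDL)^2) above the detection limit and
u = (5/6) * MDL at or below it, with EF an error fraction and MDL the
method detection limit.

The minimizer is an alternating multiplicative-update scheme for
weighted non-negative factorization (weights 1/u^2), which keeps Q
non-increasing; multiple seeded random starts are run and the lowest-Q
solution kept. Factors are normalized so each one's mean contribution
over samples is 1 (pushing units into F, so f_kj reads directly as the
mean concentration of parameter j contributed by source k) and ordered
by total explained concentration, descending.

Bounded, non-source-like variables (pH, and optionally DO) are excluded
from the fit by default; receptor-model semantics require extensive
concentration-like inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares, nnls
from scipy.sparse import csr_matrix

log = logging.getLogger(__name__)

_EPS = 1e-12

#: Variables excluded from PMF input by default (bounded / non-extensive).
DEFAULT_EXCLUDE: tuple[str, ...] = ("pH",)


@dataclass
class UncertaintyConfig:
    """Per-parameter error fraction and method detection limit.

    Defaults: EF = 0.1 everywhere; MDL = 1% of the parameter's median
    concentration (computed at build time when not supplied).
    """

    error_fraction: dict[str, float] = field(default_factory=dict)
    mdl: dict[str, float] = field(default_factory=dict)
    default_ef: float = 0.1
    default_mdl_fraction_of_median: float = 0.01


def build_uncertainty(x: float, mdl: float, ef: float) -> float:
    """Uncertainty of a single concentration value.

    Above the detection limit u = sqrt((EF*x)^2 + (0.5*MDL)^2); at or
    below it the below-detection convention u = (5/6)*MDL applies.
    """
    if mdl < 0 or ef < 0:
        raise ValueError("MDL and EF must be non-negative")
    if x > mdl:
        u = float(np.hypot(ef * x, 0.5 * mdl))
    else:
        u = (5.0 / 6.0) * mdl
    if u <= 0:
        raise ValueError(
            f"zero uncertainty for x={x} (EF={ef}, MDL={mdl}); the weighted "
            "objective would divide by zero")
    return u


def build_uncertainty_matrix(X: pd.DataFrame,
                             config: UncertaintyConfig | None = None
                             ) -> pd.DataFrame:
    """Element-wise uncertainty matrix for a concentration matrix."""
    config = config or UncertaintyConfig()
    U = pd.DataFrame(index=X.index, columns=X.columns, dtype=float)
    for col in X.columns:
        ef = config.error_fraction.get(col, config.default_ef)
        mdl = config.mdl.get(col)
        if mdl is None:
            med = float(np.nanmedian(X[col].to_numpy(dtype=float)))
            mdl = config.default_mdl_fraction_of_median * med
        U[col] = [build_uncertainty(float(v), mdl, ef) for v in X[col]]
    return U


@dataclass
class FactorModel:
    G: pd.DataFrame              # samples x p contributions, mean 1 per factor
    F: pd.DataFrame              # p x parameters profiles, parameter units
    residuals: pd.DataFrame
    Q: float
    p: int
    converged: bool
    n_iter: int
    best_start: int
    q_history: np.ndarray        # Q per iteration of the winning run
    seed: int


def _q_value(X: np.ndarray, U: np.ndarray, G: np.ndarray, F: np.ndarray) -> float:
    return float((((X - G @ F) / U) ** 2).sum())


def _nnls_sweep(Xv, Uv, G, F):
    """One exact alternating sweep: weighted NNLS for every G row, then
    every F column. Each subproblem is solved to optimality, so Q is
    non-increasing across sweeps."""
    n, m = Xv.shape
    for i in range(n):
        A = (F / Uv[i]).T            # m x p
        G[i], _ = nnls(A, Xv[i] / Uv[i])
    for j in range(m):
        A = G / Uv[:, j][:, None]    # n x p
        F[:, j], _ = nnls(A, Xv[:, j] / Uv[:, j])
    return G, F


def _polish(Xv: np.ndarray, Uv: np.ndarray, G: np.ndarray, F: np.ndarray,
            max_nfev: int):
    """Joint bounded trust-region refinement of (G, F).

    Alternating schemes converge only linearly and stall well above the
    attainable optimum on exactly factorable data; a joint Gauss-Newton
    step with the analytic sparse Jacobian finishes the descent. Returns
    (G, F) with Q no larger than on entry (the solver is monotone in
    cost and the input is its starting point).
    """
    n, m = Xv.shape
    p = G.shape[1]
    w = 1.0 / Uv
    ii, jj = np.meshgrid(np.arange(n), np.arange(m), indexing="ij")
    rows = np.repeat(np.arange(n * m), 2 * p)
    g_cols = (ii[..., None] * p + np.arange(p)).reshape(n * m, p)
    f_cols = (n * p + np.arange(p)[None, None, :] * m + jj[..., None]
              ).reshape(n * m, p)
    cols = np.concatenate([g_cols, f_cols], axis=1).ravel()

    def unpack(v):
        return v[: n * p].reshape(n, p), v[n * p:].reshape(p, m)

    def resid(v):
        g, f = unpack(v)
        return ((Xv - g @ f) * w).ravel()

    def jac(v):
        g, f = unpack(v)
        dg = -(w[..., None] * f.T[None, ...])          # n x m x p
        df = -(w[..., None] * g[:, None, :])           # n x m x p
        data = np.concatenate([dg.reshape(n * m, p),
                               df.reshape(n * m, p)], axis=1).ravel()
        return csr_matrix((data, (rows, cols)),
                          shape=(n * m, (n + m) * p))

    v0 = np.concatenate([G.ravel(), F.ravel()])
    res = least_squares(resid, v0, jac=jac, bounds=(0.0, np.inf),
                        tr_solver="lsmr", max_nfev=max_nfev,
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    return unpack(res.x)


def fit_pmf(X: pd.DataFrame, U: pd.DataFrame | None = None, p: int = 3,
            n_starts: int = 10, seed: int = 0, tol: float = 1e-9,
            max_iter: int = 2000, refine_sweeps: int = 100,
            refine_tol: float = 1e-8, polish_nfev: int = 400,
            uncertainty: UncertaintyConfig | None = None) -> FactorModel:
    """Fit the receptor model by multi-start weighted non-negative
    factorization.

    ``X`` must be non-negative (exclude pH-like bounded variables
    beforehand); ``U`` is an uncertainty matrix of the same shape, built
    from ``uncertainty`` (or defaults) when omitted. Each start runs
    multiplicative updates until the relative drop in Q falls below
    ``tol`` (or ``max_iter``), then up to ``refine_sweeps`` exact
    alternating weighted-NNLS sweeps, which sharpen convergence near
    the optimum (multiplicative updates alone slow to a crawl there).
    The lowest-Q solution over ``n_starts`` seeded random
    initializations is returned; Q is non-increasing within each run,
    and the result is reproducible for fixed (seed, n_starts).
    """
    Xv = X.to_numpy(dtype=float)
    n, m = Xv.shape
    if not 1 <= p < min(n, m):
        raise ValueError(f"need 1 <= p < min(samples, parameters) = {min(n, m)}")
    if np.any(~np.isfinite(Xv)):
        raise ValueError("X contains missing values; drop or impute first")
    if np.any(Xv < 0):
        raise ValueError("X must be non-negative (pre-screen bounded variables)")
    if U is None:
        U = build_uncertainty_matrix(X, uncertainty)
    Uv = U.to_numpy(dtype=float)
    if Uv.shape != Xv.shape:
        raise ValueError("U must match X's shape")
    if np.any(Uv <= 0):
        raise ValueError("uncertainties must be strictly positive")

    W = 1.0 / Uv ** 2
    WX = W * Xv
    rng_master = np.random.default_rng(seed)
    best = None
    col_scale = Xv.mean(axis=0).clip(min=_EPS)
    for start in range(n_starts):
        rng = np.random.default_rng(rng_master.integers(0, 2**31))
        G = rng.uniform(0.5, 1.5, size=(n, p))
        F = rng.uniform(0.5, 1.5, size=(p, m)) * col_scale / p
        q_hist = [
            _q_value(Xv, Uv, G, F)]
        converged = False
        for it in range(max_iter):
            GF = G @ F
            G *= (WX @ F.T) / ((W * GF) @ F.T + _EPS)
            G = np.maximum(G, _EPS)
            GF = G @ F
            F *= (G.T @ WX) / (G.T @ (W * GF) + _EPS)
            F = np.maximum(F, _EPS)
            q = _q_value(Xv, Uv, G, F)
            q_hist.append(q)
            if q_hist[-2] - q <= tol * max(q_hist[-2], 1e-300):
                converged = True
                break
        for _ in range(refine_sweeps):
            G, F = _nnls_sweep(Xv, Uv, G, F)
            q = _q_value(Xv, Uv, G, F)
            q_hist.append(q)
            if q_hist[-2] - q <= refine_tol * max(q_hist[-2], 1e-300):
                converged = True
                break
        if not converged:
            log.warning("fit_pmf: start %d did not meet tol within "
                        "max_iter=%d plus %d refinement sweeps",
                        start, max_iter, refine_sweeps)
        G = np.maximum(G, 0.0)
        F = np.maximum(F, 0.0)
        if best is None or q_hist[-1] < best[0]:
            best = (q_hist[-1], G, F, np.array(q_hist), start, converged)

    q, G, F, q_hist, start, converged = best
    if polish_nfev > 0:
        G2, F2 = _polish(Xv, Uv, G, F, polish_nfev)
        q2 = _q_value(Xv, Uv, G2, F2)
        if q2 <= q:  # guard against numerical no-ops
            G, F, q = G2, F2, q2
            q_hist = np.append(q_hist, q2)
    # normalize: mean contribution of each factor over samples = 1
    scale = np.maximum(G.mean(axis=0), _EPS)
    G = G / scale
    F = F * scale[:, None]
    # order factors by total explained concentration, descending
    order = np.argsort(-F.sum(axis=1))
    G, F = G[:, order], F[order, :]
    fac = [f"Factor {k + 1}" for k in range(p)]
    Gd = pd.DataFrame(G, index=X.index, columns=fac)
    Fd = pd.DataFrame(F, index=fac, columns=X.columns)
    resid = X - pd.DataFrame(G @ F, index=X.index, columns=X.columns)
    return FactorModel(G=Gd, F=Fd, residuals=resid, Q=q, p=p,
                       converged=converged, n_iter=len(q_hist) - 1,
                       best_start=start, q_history=q_hist, seed=seed)


# ---------------------------------------------------------------------------
# Apportionment


def r2_per_variable(observed, reconstructed) -> float:
    """Squared Pearson correlation between observed and reconstructed series."""
    obs = np.asarray(observed, dtype=float)
    rec = np.asarray(reconstructed, dtype=float)
    if obs.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.std(obs) == 0 or np.std(rec) == 0:
        log.warning("r2_per_variable: zero-variance series; R^2 undefined")
        return float("nan")
    r, _ = stats.pearsonr(obs, rec)
    return float(r ** 2)


def contribution_percentages(concentrations) -> np.ndarray:
    """Percentage split of per-factor concentration contributions.

    Returns 100 * c_k / sum_k c_k; the shares sum to 100 by
    construction.
    """
    c = np.asarray(concentrations, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("zero total contribution; percentages undefined")
    return 100.0 * c / total


def apportion(model: FactorModel, X: pd.DataFrame) -> pd.DataFrame:
    """Source-apportionment table: per parameter, each factor's mean
    concentration contribution, its percentage share, and the R^2
    between observed and reconstructed series.

    The concentration contribution of factor k to parameter j is the
    sample mean of g_ik * f_kj.
    """
    G = model.G.to_numpy()
    F = model.F.to_numpy()
    recon = G @ F
    rows = []
    for j, param in enumerate(model.F.columns):
        conc = (G * F[:, j][None, :]).mean(axis=0)
        try:
            pct = contribution_percentages(conc)
        except ValueError:
            log.warning("apportion: zero total contribution for %s", param)
            pct = np.full(model.p, np.nan)
        row = {"parameter": param}
        for k in range(model.p):
            row[f"conc_factor{k + 1}"] = conc[k]
        for k in range(model.p):
            row[f"pct_factor{k + 1}"] = pct[k]
        row["r2"] = r2_per_variable(X[param].to_numpy(), recon[:, j])
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")


def match_factors(F_fitted: pd.DataFrame, F_true: np.ndarray) -> tuple[list[int], np.ndarray]:
    """Best-permutation cosine matching of fitted profiles to true ones.

    Returns the permutation (fitted index for each true factor) and the
    per-factor cosine similarities under it.
    """
    from itertools import permutations

    Ff = F_fitted.to_numpy() if hasattr(F_fitted, "to_numpy") else np.asarray(F_fitted)
    Ft = np.asarray(F_true, dtype=float)
    p = Ft.shape[0]
    if Ff.shape != Ft.shape:
        raise ValueError("profile matrices must have the same shape")

    def cos(u, v):
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        return float(u @ v / (nu * nv)) if nu > 0 and nv > 0 else 0.0

    sim = np.array([[cos(Ft[i], Ff[j]) for j in range(p)] for i in range(p)])
    best_perm, best_total = None, -np.inf
    for perm in permutations(range(p)):
        total = sum(sim[i, perm[i]] for i in range(p))
        if total > best_total:
            best_total, best_perm = total, perm
    return list(best_perm), np.array([sim[i, best_perm[i]] for i in range(p)])
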