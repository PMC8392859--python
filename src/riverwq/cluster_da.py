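"""Site grouping by Bray-Curtis hierarchical clustering and
linear / stepwise discriminant analysis with classification matrices.

Clustering operates on per-site mean parameter vectors with Bray-Curtis
dissimilarity (abundance semantics: raw, unstandardized concentrations
by default) and an agglomerative linkage; site groups come from cutting
the dendrogram at a similarity threshold (default 60%).

Discriminant analysis follows the classical Wilks'-lambda formulation:
Lambda(subset) = det(W)/det(T) with W and T the within-group and total
SSCP matrices restricted to the subset. Stepwise selection enters the
variable with the largest partial F when it exceeds ``f_enter`` and
removes entered variables whose partial F drops below ``f_remove``
(SPSS-convention defaults 3.84 / 2.71). Classification uses Fisher
linear classification functions with equal priors and resubstitution
counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Bray-Curtis clustering


def bray_curtis(a, b) -> float:
    """Bray-Curtis similarity: 1 - sum|a-b| / sum(a+b), in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have the same length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("Bray-Curtis requires non-negative vectors")
    denom = (a + b).sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero; similarity undefined")
    return 1.0 - np.abs(a - b).sum() / denom


@dataclass
class ClusterTree:
    labels: list[str]            # leaf site ids, input order
    merges: pd.DataFrame         # scipy-style: left, right, dissimilarity, size
    linkage_matrix: np.ndarray
    linkage_method: str
    cut_similarity: float
    groups: dict[str, int]       # site -> 1-based group id

    def newick(self) -> str:
        """Newick string with branch lengths from merge dissimilarities."""
        root = to_tree(self.linkage_matrix)

        def walk(node, parent_height):
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(root, root.dist) + ";"


def site_means(matrix) -> pd.DataFrame:
    """Per-site mean parameter vector from a WaterQualityMatrix."""
    df = pd.concat([matrix.meta[["site_id"]], matrix.values], axis=1)
    return df.groupby("site_id").mean()


def cluster_sites(means: pd.DataFrame, linkage_method: str = "average",
                  cut_similarity: float = 0.60,
                  range_normalize: bool = False) -> ClusterTree:
    """Agglomerative clustering of sites on Bray-Curtis dissimilarity.

    ``means`` is sites x parameters (non-negative). Sites with
    all-missing rows are dropped with a warning; remaining missing
    entries are treated as zero abundance. Groups are the dendrogram
    branches below dissimilarity ``1 - cut_similarity``; a cut at
    similarity 1.0 therefore yields singletons. ``range_normalize``
    rescales each parameter to [0, 1] first, preventing large-unit
    parameters from dominating (off by default, matching abundance
    semantics).
    """
    if linkage_method not in ("single", "complete", "average"):
        raise ValueError("linkage must be single, complete or average")
    means = means.copy()
    all_missing = means.isna().all(axis=1)
    if all_missing.any():
        log.warning("cluster_sites: dropping all-missing sites %s",
                    list(means.index[all_missing]))
        means = means[~all_missing]
    if len(means) < 2:
        raise ValueError("need at least 2 sites")
    X = means.fillna(0.0).to_numpy(dtype=float)
    if range_normalize:
        rng = X.max(axis=0) - X.min(axis=0)
        rng[rng == 0] = 1.0
        X = (X - X.min(axis=0)) / rng
    d = pdist(X, metric="braycurtis")
    Z = linkage(d, method=linkage_method)
    ids = fcluster(Z, t=1.0 - cut_similarity, criterion="distance")
    # renumber groups deterministically by order of first appearance
    remap: dict[int, int] = {}
    for g in ids:
        remap.setdefault(int(g), len(remap) + 1)
    groups = {site: remap[int(g)] for site, g in zip(means.index, ids)}
    merges = pd.DataFrame(Z, columns=["left", "right", "dissimilarity", "size"])
    return ClusterTree(labels=list(means.index), merges=merges,
                       linkage_matrix=Z, linkage_method=linkage_method,
                       cut_similarity=cut_similarity, groups=groups)


# ---------------------------------------------------------------------------
# Discriminant analysis


@dataclass
class DiscriminantModel:
    variables: list[str]               # selected, in entry order
    steps: list[dict]                  # per step: action, variable, wilks, F
    group_labels: list[str]
    means: pd.DataFrame                # groups x selected variables
    pooled_cov: pd.DataFrame
    coef: pd.DataFrame                 # classification-function coefficients
    intercept: pd.Series
    wilks_lambda: float
    warnings: list[str] = field(default_factory=list)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Assign each row to the group with the largest classification score."""
        if not self.variables:
            # empty model: fall back to priors (equal -> first label)
            return np.array([self.group_labels[0]] * len(X))
        V = X[self.variables].to_numpy(dtype=float)
        scores = V @ self.coef.to_numpy().T + self.intercept.to_numpy()
        return np.asarray(self.group_labels)[np.argmax(scores, axis=1)]


def _sscp(X: np.ndarray, groups: np.ndarray):
    """Within-group and total SSCP matrices."""
    grand = X.mean(axis=0)
    T = (X - grand).T @ (X - grand)
    W = np.zeros_like(T)
    for g in np.unique(groups):
        Xg = X[groups == g]
        cg = Xg - Xg.mean(axis=0)
        W += cg.T @ cg
    return W, T


def wilks_lambda(X: np.ndarray, groups: np.ndarray, idx: list[int]) -> float:
    """Wilks' Lambda det(W)/det(T) on the variable subset ``idx``."""
    if not idx:
        return 1.0
    W, T = _sscp(X[:, idx], groups)
    sW, ldW = np.linalg.slogdet(W)
    sT, ldT = np.linalg.slogdet(T)
    if sW <= 0 or sT <= 0:
        raise np.linalg.LinAlgError("singular SSCP matrix")
    return float(np.exp(ldW - ldT))


def _partial_f(lam_small: float, lam_big: float, n: int, g: int,
               p_in: int) -> float:
    """Partial F for adding one variable to a p_in-variable model."""
    if lam_big <= 0:
        return np.inf
    return (lam_small / lam_big - 1.0) * (n - g - p_in) / (g - 1)


def stepwise_da(matrix: pd.DataFrame, groups, f_enter: float = 3.84,
                f_remove: float = 2.71) -> DiscriminantModel:
    """Stepwise discriminant analysis driven by Wilks' Lambda partial F.

    ``matrix`` is samples x candidate variables (complete cases only:
    rows with missing values are dropped), ``groups`` the per-sample
    class labels. Variables enter one at a time (largest partial F, if
    >= ``f_enter``) and already-entered variables are removed when their
    partial F falls below ``f_remove``. If nothing qualifies for entry
    an empty model is returned with a warning.
    """
    X_df = matrix.dropna(axis=0, how="any")
    y = pd.Series(np.asarray(groups), index=matrix.index).loc[X_df.index]
    X = X_df.to_numpy(dtype=float)
    labels = y.to_numpy()
    names = list(X_df.columns)
    uniq = sorted(pd.unique(labels).tolist())
    g, n = len(uniq), len(X_df)
    if g < 2:
        raise ValueError("need at least 2 groups")
    counts = pd.Series(labels).value_counts()
    if counts.min() <= X.shape[1]:
        log.warning("stepwise_da: smallest group (n=%d) not larger than the "
                    "candidate variable count (%d)", counts.min(), X.shape[1])

    selected: list[int] = []
    steps: list[dict] = []
    warnings: list[str] = []
    changed = True
    while changed:
        changed = False
        # entry
        lam_cur = wilks_lambda(X, labels, selected)
        best_f, best_j, best_lam = -np.inf, None, None
        for j in range(len(names)):
            if j in selected:
                continue
            try:
                lam_new = wilks_lambda(X, labels, selected + [j])
            except np.linalg.LinAlgError:
                continue
            f = _partial_f(lam_cur, lam_new, n, g, len(selected))
            if f > best_f:
                best_f, best_j, best_lam = f, j, lam_new
        if best_j is not None and best_f >= f_enter:
            selected.append(best_j)
            steps.append({"action": "enter", "variable": names[best_j],
                          "wilks": best_lam, "F": best_f})
            changed = True
        # removal
        removed = True
        while removed and len(selected) > 1:
            removed = False
            lam_cur = wilks_lambda(X, labels, selected)
            worst_f, worst_j = np.inf, None
            for j in selected:
                others = [k for k in selected if k != j]
                lam_wo = wilks_lambda(X, labels, others)
                f = _partial_f(lam_wo, lam_cur, n, g, len(others))
                if f < worst_f:
                    worst_f, worst_j = f, j
            if worst_j is not None and worst_f < f_remove:
                selected.remove(worst_j)
                steps.append({"action": "remove", "variable": names[worst_j],
                              "wilks": wilks_lambda(X, labels, selected),
                              "F": worst_f})
                removed = changed = True
    if not selected:
        warnings.append("no variable met the entry criterion; empty model")
        log.warning("stepwise_da: %s", warnings[-1])
    return _fit_classifier(X_df, y, [names[j] for j in selected], steps,
                           warnings)


def standard_da(matrix: pd.DataFrame, groups) -> DiscriminantModel:
    """Standard-mode discriminant analysis using every candidate variable."""
    X_df = matrix.dropna(axis=0, how="any")
    y = pd.Series(np.asarray(groups), index=matrix.index).loc[X_df.index]
    return _fit_classifier(X_df, y, list(X_df.columns), steps=[], warnings=[])


def _fit_classifier(X_df: pd.DataFrame, y: pd.Series, variables: list[str],
                    steps: list[dict], warnings: list[str]) -> DiscriminantModel:
    labels = y.to_numpy()
    uniq = sorted(pd.unique(labels).tolist())
    n, g = len(X_df), len(uniq)
    if not variables:
        empty = pd.DataFrame(index=[str(u) for u in uniq])
        return DiscriminantModel(
            variables=[], steps=steps, group_labels=[str(u) for u in uniq],
            means=empty, pooled_cov=pd.DataFrame(), coef=empty,
            intercept=pd.Series(0.0, index=[str(u) for u in uniq]),
            wilks_lambda=1.0, warnings=warnings)
    X = X_df[variables].to_numpy(dtype=float)
    W, _ = _sscp(X, labels)
    pooled = W / (n - g)
    try:
        pinv = np.linalg.inv(pooled)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular pooled within-group covariance over {variables}; "
            "collinear variables") from exc
    means = np.vstack([X[labels == u].mean(axis=0) for u in uniq])
    coef = means @ pinv                               # one row per group
    intercept = -0.5 * np.einsum("ij,ij->i", coef, means)  # equal priors
    lam = wilks_lambda(X_df[variables].to_numpy(dtype=float), labels,
                       list(range(len(variables))))
    return DiscriminantModel(
        variables=variables, steps=steps,
        group_labels=[str(u) for u in uniq],
        means=pd.DataFrame(means, index=[str(u) for u in uniq],
                           columns=variables),
        pooled_cov=pd.DataFrame(pooled, index=variables, columns=variables),
        coef=pd.DataFrame(coef, index=[str(u) for u in uniq],
                          columns=variables),
        intercept=pd.Series(intercept, index=[str(u) for u in uniq]),
        wilks_lambda=lam, warnings=warnings)


def classification_matrix(model: DiscriminantModel, matrix: pd.DataFrame,
                          groups) -> tuple[pd.DataFrame, float]:
    """Resubstitution classification matrix and percent correctly assigned."""
    X_df = matrix.dropna(axis=0, how="any")
    y = pd.Series(np.asarray(groups), index=matrix.index).loc[X_df.index]
    actual = y.astype(str).to_numpy()
    uniq = model.group_labels
    if len(uniq) == 1:
        log.warning("classification_matrix: single group is degenerate")
    pred = model.predict(X_df)
    cm = pd.DataFrame(0, index=uniq, columns=uniq)
    for a, p in zip(actual, pred):
        cm.loc[a, p] += 1
    pct = 100.0 * np.trace(cm.to_numpy()) / cm.to_numpy().sum()
    return cm, float(pct)
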