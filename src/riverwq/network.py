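"""Significance-filtered Pearson correlation networks and the empirical
nutrient / chlorophyll / coliform regressions, plus pre/post-weir fold
changes.

Network edges connect parameter pairs whose Pearson correlation is
significant at p < alpha (default 0.05), with the significance of r
computed from t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
Edges carry r, p, n and sign (positive/negative, the green/red
convention of co-occurrence plots). Pairwise-complete observations are
used per edge so one missing parameter does not erase a sample's other
correlations; no multiple-testing correction is applied by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


def correlation_network(matrix: pd.DataFrame, alpha: float = 0.05,
                        bonferroni: bool = False) -> nx.Graph:
    """Pearson co-occurrence network of a samples x parameters matrix.

    Every parameter is a node; an edge (i, j) is kept when the two-sided
    p-value of the pairwise-complete Pearson correlation is below
    ``alpha`` (divided by the number of tested pairs under
    ``bonferroni``). Pairs with fewer than 4 complete observations or a
    constant column are skipped with a warning.
    """
    cols = list(matrix.columns)
    graph = nx.Graph(alpha=alpha)
    graph.add_nodes_from(cols)
    pairs = [(i, j) for i in range(len(cols)) for j in range(i + 1, len(cols))]
    threshold = alpha / len(pairs) if bonferroni and pairs else alpha
    for i, j in pairs:
        a, b = cols[i], cols[j]
        sub = matrix[[a, b]].dropna()
        n = len(sub)
        if n < 4:
            log.warning("correlation_network: %s-%s has %d complete pairs "
                        "(<4); skipped", a, b, n)
            continue
        if sub[a].nunique() == 1 or sub[b].nunique() == 1:
            log.warning("correlation_network: constant column in pair %s-%s; "
                        "edge undefined", a, b)
            continue
        r, p = stats.pearsonr(sub[a], sub[b])
        if p < threshold:
            graph.add_edge(a, b, r=float(r), p=float(p), n=n,
                           sign="positive" if r >= 0 else "negative")
    return graph


def edge_table(graph: nx.Graph) -> pd.DataFrame:
    """Edge list (source, target, r, p, n, sign) of a correlation network."""
    rows = [
        {"source": u, "target": v, **d} for u, v, d in graph.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["source", "target", "r", "p", "n", "sign"])


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


@dataclass(frozen=True)
class RegressionFit:
    response: str
    predictor: str
    transform: str     # "log10" | "none"
    slope: float
    intercept: float
    r2: float
    n: int


def empirical_regression(response, predictor, log_transform: bool = True,
                         response_name: str = "y",
                         predictor_name: str = "x") -> RegressionFit:
    """Single-predictor OLS, on log10-transformed pairs by default.

    The log-log form is the standard empirical model for
    nutrient-chlorophyll (and similar driver-response) relationships in
    limnology. Non-positive values are dropped under the log transform,
    with a logged count; R^2 is the squared Pearson correlation of the
    (transformed) pairs.
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    if log_transform:
        pos = keep & (x > 0) & (y > 0)
        dropped = int(keep.sum() - pos.sum())
        if dropped:
            log.info("empirical_regression: dropped %d non-positive pairs "
                     "under log transform", dropped)
        x, y = np.log10(x[pos]), np.log10(y[pos])
    else:
        x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 usable pairs")
    if np.std(x) == 0:
        raise ValueError("zero predictor variance")
    res = stats.linregress(x, y)
    return RegressionFit(response=response_name, predictor=predictor_name,
                         transform="log10" if log_transform else "none",
                         slope=float(res.slope), intercept=float(res.intercept),
                         r2=float(res.rvalue ** 2), n=int(x.size))


def fold_change(pre_values, post_values) -> tuple[float, str]:
    """Fold change between period means, reported in the direction of change.

    A decrease is reported as mean(pre)/mean(post) with label
    "decrease"; an increase as mean(post)/mean(pre) with "increase", so
    the ratio is always >= 1 and reads "k-fold <direction>".
    """
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    pre = pre[np.isfinite(pre)]
    post = post[np.isfinite(post)]
    if pre.size == 0 or post.size == 0:
        raise ValueError("both groups must be non-empty")
    mp, mq = pre.mean(), post.mean()
    if mp <= 0 or mq <= 0:
        raise ValueError("fold change requires positive means")
    if mq == mp:
        return 1.0, "no change"
    if mq < mp:
        return float(mp / mq), "decrease"
    return float(mq / mp), "increase"
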