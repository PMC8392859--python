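"""Mann-Kendall monotonic trend test with tie-corrected variance.

The test statistic is S = sum_{i<j} sgn(x_j - x_i). Under the null of
no trend S has mean zero and variance

    Var(S) = [n(n-1)(2n+5) - sum_t t(t-1)(2t+5)] / 18,

the sum running over tied groups of size t. The normal deviate uses the
classical continuity correction, Z = (S-1)/sqrt(Var S) for S>0, 0 for
S=0 and (S+1)/sqrt(Var S) for S<0, with a two-sided p-value from the
standard normal. No multiple-testing correction is applied by default
when testing many site/parameter series; a Benjamini-Hochberg option is
available.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import PARAMETERS, WaterQualityMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrendResult:
    s: int
    var_s: float
    z: float
    p: float
    direction: str  # "increasing" | "decreasing" | "no trend"
    n: int


def mk_test(series, alpha: float = 0.05) -> TrendResult:
    """Mann-Kendall trend test on a time-ordered series.

    Missing values are dropped (positions logged). Requires n >= 4 after
    dropping; below 8 the normal approximation is rough and a warning is
    emitted. ``direction`` is "no trend" when p >= alpha, else the sign
    of S.
    """
    x = np.asarray(series, dtype=float)
    missing = np.where(~np.isfinite(x))[0]
    if missing.size:
        log.info("mk_test: dropped %d missing values at positions %s",
                 missing.size, missing.tolist())
        x = x[np.isfinite(x)]
    n = x.size
    if n < 4:
        raise ValueError(f"mk_test needs at least 4 values, got {n}")
    if n < 8:
        log.warning("mk_test: n=%d < 8, normal approximation is rough", n)

    diff = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diff, k=1).sum())

    ties = Counter(x.tolist())
    tie_term = sum(t * (t - 1) * (2 * t + 5) for t in ties.values() if t > 1)
    var_s = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0

    if var_s == 0:  # all values tied
        log.warning("mk_test: all values tied; no trend by construction")
        return TrendResult(s=0, var_s=0.0, z=0.0, p=1.0, direction="no trend", n=n)

    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    if p < alpha:
        direction = "increasing" if s > 0 else "decreasing"
    else:
        direction = "no trend"
    return TrendResult(s=s, var_s=float(var_s), z=float(z), p=float(p),
                       direction=direction, n=n)


def trend_report(
    matrix: WaterQualityMatrix,
    grouping: str = "site",
    alpha: float = 0.05,
    annual_means: bool = False,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Mann-Kendall test per (group, parameter).

    ``grouping`` is "site" (one series per site) or "river-wide" (dates
    pooled across sites by mean). Series are monthly by default; with
    ``annual_means`` calendar-year means are tested instead. Groups with
    fewer than 4 time points are skipped with a log entry. Without
    ``bh_correct`` no multiple-comparison adjustment is applied (each
    series is reported at its raw p-value); with it, Benjamini-Hochberg
    adjusted p-values drive the direction call.
    """
    if grouping not in ("site", "river-wide"):
        raise ValueError("grouping must be 'site' or 'river-wide'")
    df = pd.concat([matrix.meta[["site_id", "date"]], matrix.values], axis=1)
    if grouping == "river-wide":
        df = df.assign(site_id="all")
    rows = []
    for site, sub in df.groupby("site_id"):
        sub = sub.sort_values("date")
        for param in PARAMETERS:
            series = sub.set_index("date")[param].dropna()
            # river-wide pooling: average sites within each date
            series = series.groupby(level=0).mean()
            if annual_means:
                series = series.groupby([d.year for d in series.index]).mean()
            if len(series) < 4:
                log.info("trend_report: skipping %s/%s (n=%d < 4)",
                         site, param, len(series))
                continue
            r = mk_test(series.to_numpy(), alpha=alpha)
            rows.append({"site": site, "parameter": param, "n": r.n, "S": r.s,
                         "var_S": r.var_s, "Z": r.z, "p": r.p,
                         "direction": r.direction})
    out = pd.DataFrame(rows)
    if bh_correct and not out.empty:
        out["p_adj"] = _benjamini_hochberg(out["p"].to_numpy())
        sig = out["p_adj"] < alpha
        out["direction"] = np.where(
            sig, np.where(out["S"] > 0, "increasing", "decreasing"), "no trend")
    else:
        log.info("trend_report: %d tests at raw alpha=%.3g "
                 "(no multiple-comparison correction)", len(out), alpha)
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
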