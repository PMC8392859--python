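"""Weighted-arithmetic Water Quality Index.

The index aggregates the monitored parameters (all except water
temperature) into a single dimensionless score. Each parameter n has a
standard desirable value S_n and an ideal pure-water value V_0 (zero for
every parameter except pH, whose ideal is 7, and DO, whose ideal is the
saturation value 14.6 mg/L). The three steps are

1. unit weights  W_n = K / S_n  with  K = 1 / sum(1/S_n), so sum W_n = 1;
2. sub-indices   Q_n = (V_n - V_0) / (S_n - V_0) * 100;
3. overall       WQI = sum(W_n Q_n) / sum(W_n).

For DO the denominator S_n - V_0 is negative, so measurements below
saturation produce a positive sub-index — the signed formula applies
verbatim. Scores map to usability bands: 0-25 excellent, >25-50 good,
>50-75 poor, >75-100 very poor, >100 unsuitable.

The default standards table is an editable package default assembled
from the pollution thresholds used elsewhere in this package; any
regulatory table can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core_data import PARAMETERS

#: Parameters entering the index (water temperature excluded).
WQI_PARAMETERS: tuple[str, ...] = tuple(p for p in PARAMETERS if p != "WT")

DEFAULT_STANDARDS: dict[str, float] = {
    "pH": 8.5,       # upper permissible pH
    "DO": 5.0,       # mg/L minimum desirable oxygen
    "EC": 300.0,     # uS/cm severe-pollution threshold
    "TSS": 25.0,     # mg/L
    "TP": 100.0,     # ug/L
    "TN": 1.5,       # mg/L eutrophication threshold
    "BOD": 5.0,      # mg/L organic-pollution threshold
    "COD": 7.0,      # mg/L organic-pollution threshold
    "CHL-a": 30.0,   # ug/L eutrophication threshold
    "TCB": 5000.0,   # MPN/100 mL
}

DEFAULT_IDEALS: dict[str, float] = {p: 0.0 for p in WQI_PARAMETERS}
DEFAULT_IDEALS["pH"] = 7.0
DEFAULT_IDEALS["DO"] = 14.6

DEFAULT_BANDS: tuple[tuple[float, str], ...] = (
    (25.0, "excellent"),
    (50.0, "good"),
    (75.0, "poor"),
    (100.0, "very poor"),
)
UNSUITABLE = "unsuitable"


@dataclass(frozen=True)
class StandardsTable:
    """Per-parameter standard desirable values S_n and ideals V_0."""

    standards: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STANDARDS))
    ideals: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_IDEALS))

    def __post_init__(self) -> None:
        if "WT" in self.standards:
            raise ValueError("water temperature is excluded from the WQI")
        unknown = set(self.standards) - set(WQI_PARAMETERS)
        if unknown:
            raise ValueError(f"unknown parameters in standards: {sorted(unknown)}")
        for p, s in self.standards.items():
            if s <= 0:
                raise ValueError(f"standard for {p} must be positive")
            if s == self.ideals.get(p, 0.0):
                raise ValueError(f"S_n equals V_0 for {p}; sub-index undefined")

    @property
    def parameters(self) -> list[str]:
        return [p for p in WQI_PARAMETERS if p in self.standards]


@dataclass(frozen=True)
class WqiResult:
    k: float
    weights: dict[str, float]      # W_n over the parameters actually present
    subindices: dict[str, float]   # Q_n (%)
    wqi: float
    quality_class: str


def compute_unit_weights(standards: StandardsTable) -> tuple[float, dict[str, float]]:
    """Unit weights W_n = K/S_n with K = 1/sum(1/S_n); the weights sum to 1."""
    params = standards.parameters
    if not params:
        raise ValueError("standards table is empty")
    k = 1.0 / sum(1.0 / standards.standards[p] for p in params)
    return k, {p: k / standards.standards[p] for p in params}


def compute_subindex(v_n: float, s_n: float, v_0: float = 0.0) -> float:
    """Sub-index Q_n = (V_n - V_0)/(S_n - V_0) * 100 (signed formula)."""
    if s_n == v_0:
        raise ValueError("S_n equals V_0; sub-index undefined")
    return (v_n - v_0) / (s_n - v_0) * 100.0


def compute_wqi(sample: dict[str, float],
                standards: StandardsTable | None = None,
                bands: tuple[tuple[float, str], ...] = DEFAULT_BANDS) -> WqiResult:
    """Overall WQI of one sample (parameter -> measured value).

    Missing parameters are handled by renormalising the unit weights over
    the parameters present, keeping the unity constraint meaningful per
    sample; WT and parameters without a standard are ignored.
    """
    standards = standards or StandardsTable()
    present = [p for p in standards.parameters
               if p in sample and pd.notna(sample[p])]
    if not present:
        raise ValueError("no WQI parameter present in sample")
    _, weights_all = compute_unit_weights(standards)
    wsum = sum(weights_all[p] for p in present)
    weights = {p: weights_all[p] / wsum for p in present}
    sub = {
        p: compute_subindex(float(sample[p]), standards.standards[p],
                            standards.ideals.get(p, 0.0))
        for p in present
    }
    wqi = sum(weights[p] * sub[p] for p in present)
    k, _ = compute_unit_weights(standards)
    return WqiResult(k=k, weights=weights, subindices=sub, wqi=wqi,
                     quality_class=classify_wqi(wqi, bands))


def classify_wqi(wqi: float,
                 bands: tuple[tuple[float, str], ...] = DEFAULT_BANDS) -> str:
    """Quality class of a WQI score; band upper edges are inclusive."""
    if wqi < 0:
        raise ValueError("WQI must be non-negative")
    for edge, label in bands:
        if wqi <= edge:
            return label
    return UNSUITABLE


def wqi_report(matrix, standards: StandardsTable | None = None,
               by: tuple[str, ...] = ("site_id", "season")) -> pd.DataFrame:
    """Per-group WQI summary (group columns, n, mean WQI, class).

    ``matrix`` is a :class:`~riverwq.core_data.WaterQualityMatrix`; each
    sample row gets its own WQI, then scores are averaged per group.
    """
    standards = standards or StandardsTable()
    scores = []
    for idx in matrix.values.index:
        sample = matrix.values.loc[idx].to_dict()
        try:
            scores.append(compute_wqi(sample, standards).wqi)
        except ValueError:
            scores.append(float("nan"))
    df = matrix.meta.copy()
    df["wqi"] = scores
    grouped = df.groupby(list(by), observed=True)["wqi"].agg(["count", "mean"])
    grouped = grouped.rename(columns={"count": "n", "mean": "mean_wqi"})
    grouped["quality_class"] = [classify_wqi(v) if pd.notna(v) else "n/a"
                                for v in grouped["mean_wqi"]]
    return grouped.reset_index()
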