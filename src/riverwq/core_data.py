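"""Data model, long/wide I/O, season and weir-period assignment, and
threshold-based ecological classifications.

The monitoring vocabulary is the fixed set of 11 physicochemical and
biological parameters measured monthly at river sites: pH (unitless),
water temperature WT (degC), dissolved oxygen DO (mg/L), electrical
conductivity EC (uS/cm), total suspended solids TSS (mg/L), total
phosphorus TP (ug/L), total nitrogen TN (mg/L), biological and chemical
oxygen demand BOD/COD (mg/L), chlorophyll-a CHL-a (ug/L) and total
coliform bacteria TCB (MPN/100 mL).

Unit convention: TP is carried in ug/L and TN in mg/L; the TN/TP mass
ratio is computed after converting TN to ug/L so that both masses share
a common basis.
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Closed vocabulary of monitored parameters, in canonical column order.
PARAMETERS: tuple[str, ...] = (
    "pH", "WT", "DO", "EC", "TSS", "TP", "TN", "BOD", "COD", "CHL-a", "TCB",
)

SEASONS = ("premonsoon", "monsoon", "postmonsoon")
PERIODS = ("pre-weir", "transition", "post-weir")
TIERS = ("HP", "MP", "LP", "unknown")


@dataclass(frozen=True)
class MonitoringRecord:
    """One (site, date, parameter, value) observation."""

    site_id: str
    timestamp: dt.date
    parameter: str
    value: float

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if not np.isfinite(self.value):
            raise ValueError(f"non-finite value for {self.parameter}")
        if self.value < 0:
            raise ValueError(f"negative value {self.value} for {self.parameter}")
        if self.parameter == "pH" and not (0.0 <= self.value <= 14.0):
            raise ValueError(f"pH {self.value} outside [0, 14]")


@dataclass(frozen=True)
class PeriodBoundaries:
    """Weir-construction period boundaries.

    Dates up to and including ``pre_end`` are "pre-weir", dates from
    ``post_start`` on are "post-weir", and dates in between form a
    "transition" window (the construction year, during which both the
    weirs and upgraded treatment facilities were commissioned) that is
    excluded from pre/post contrasts by default.
    """

    pre_end: dt.date = dt.date(2011, 12, 31)
    post_start: dt.date = dt.date(2013, 1, 1)

    def __post_init__(self) -> None:
        if self.pre_end >= self.post_start:
            raise ValueError("pre_end must precede post_start")


@dataclass(frozen=True)
class ThresholdRuleSet:
    """Ecological classification thresholds.

    Trophic-state cutoffs follow the river/stream eutrophication
    criteria (TP > 75 ug/L, TN > 1.5 mg/L, CHL-a > 30 ug/L); BOD > 5 and
    COD > 7 mg/L flag organic pollution; EC > 300 uS/cm flags severe
    ionic pollution; the TCB band edges separate little / moderate /
    critical / strong / excessive coliform pollution; a TN/TP mass ratio
    above ``tn_tp_p_limit`` indicates phosphorus-limited algal growth.
    """

    tp_eutrophic: float = 75.0          # ug/L
    tn_eutrophic: float = 1.5           # mg/L
    chl_eutrophic: float = 30.0         # ug/L
    bod_organic: float = 5.0            # mg/L
    cod_organic: float = 7.0            # mg/L
    ec_severe: float = 300.0            # uS/cm
    tcb_edges: tuple[float, ...] = (500.0, 1e4, 1e5, 1e6)  # MPN/100 mL
    tcb_labels: tuple[str, ...] = (
        "little pollution", "moderate pollution", "critical pollution",
        "strong pollution", "excessive pollution",
    )
    tn_tp_p_limit: float = 20.0

    def __post_init__(self) -> None:
        for v in (self.tp_eutrophic, self.tn_eutrophic, self.chl_eutrophic,
                  self.bod_organic, self.cod_organic, self.ec_severe,
                  self.tn_tp_p_limit):
            if v <= 0:
                raise ValueError("thresholds must be positive")
        edges = self.tcb_edges
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("TCB band edges must be strictly increasing")
        if len(self.tcb_labels) != len(edges) + 1:
            raise ValueError("need one more label than band edges")


@dataclass
class WaterQualityMatrix:
    """Samples x parameters matrix with per-row metadata.

    ``values`` has one row per (site, date) and exactly the 11 canonical
    parameter columns (NaN = missing); ``meta`` shares the index and
    carries site_id, date, season, period and pollution tier.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(PARAMETERS):
            raise ValueError("value columns must be the canonical 11 parameters")
        if not self.values.index.equals(self.meta.index):
            raise ValueError("values and meta must share an index")

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missing-value mask (True where absent)."""
        return self.values.isna()

    def to_long(self) -> list[MonitoringRecord]:
        """Flatten back to records, dropping missing cells."""
        out: list[MonitoringRecord] = []
        for idx, row in self.values.iterrows():
            site = self.meta.at[idx, "site_id"]
            date = self.meta.at[idx, "date"]
            for param, val in row.items():
                if pd.notna(val):
                    out.append(MonitoringRecord(site, date, str(param), float(val)))
        return out

    def subset(self, mask: pd.Series) -> "WaterQualityMatrix":
        return WaterQualityMatrix(self.values[mask].copy(), self.meta[mask].copy())


def season_of(month: int) -> str:
    """Monsoon-stratified season of a calendar month.

    January-June is premonsoon, July-August the summer monsoon, and
    September-December postmonsoon.
    """
    if not (isinstance(month, (int, np.integer)) and 1 <= month <= 12):
        raise ValueError(f"month must be an integer in 1..12, got {month!r}")
    if month <= 6:
        return "premonsoon"
    if month <= 8:
        return "monsoon"
    return "postmonsoon"


def period_of(date: dt.date, boundaries: PeriodBoundaries | None = None) -> str:
    """Weir period ("pre-weir" / "transition" / "post-weir") of a date."""
    b = boundaries or PeriodBoundaries()
    if date <= b.pre_end:
        return "pre-weir"
    if date >= b.post_start:
        return "post-weir"
    return "transition"


@dataclass
class ReadReport:
    """Row-level diagnostics from :func:`read_long_csv`."""

    n_rows: int = 0
    n_parsed: int = 0
    rejects: list[tuple[int, str]] = field(default_factory=list)  # (row no, reason)


def read_long_csv(path) -> tuple[list[MonitoringRecord], ReadReport]:
    """Read long-format monitoring CSV (site_id, date, parameter, value).

    Every row is either parsed into a :class:`MonitoringRecord` or
    rejected with a row-numbered reason in the report. Dates must be
    ISO-8601 (YYYY-MM-DD); parameters must belong to the closed
    vocabulary.
    """
    records: list[MonitoringRecord] = []
    report = ReadReport()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"site_id", "date", "parameter", "value"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"header must contain {sorted(required)}")
        for i, row in enumerate(reader, start=2):  # 1-based, after header
            report.n_rows += 1
            try:
                date = dt.date.fromisoformat(row["date"].strip())
            except ValueError:
                report.rejects.append((i, f"unparseable date {row['date']!r}"))
                continue
            try:
                value = float(row["value"])
            except ValueError:
                report.rejects.append((i, f"unparseable value {row['value']!r}"))
                continue
            try:
                rec = MonitoringRecord(row["site_id"].strip(), date,
                                       row["parameter"].strip(), value)
            except ValueError as exc:
                report.rejects.append((i, str(exc)))
                continue
            records.append(rec)
            report.n_parsed += 1
    if report.n_rows == 0:
        log.warning("read_long_csv: %s contained a header but no data rows", path)
    for rowno, reason in report.rejects:
        log.warning("read_long_csv: row %d rejected (%s)", rowno, reason)
    return records, report


def write_long_csv(records: list[MonitoringRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["site_id", "date", "parameter", "value"])
        for r in records:
            writer.writerow([r.site_id, r.timestamp.isoformat(), r.parameter,
                             repr(r.value)])


def pivot_to_matrix(
    records: list[MonitoringRecord],
    boundaries: PeriodBoundaries | None = None,
    site_tiers: dict[str, str] | None = None,
) -> WaterQualityMatrix:
    """Pivot records to one row per (site, date).

    Duplicate (site, date, parameter) observations are averaged (monthly
    replicates are common in agency exports); absent observations are
    left missing. Season and weir period are filled in from the date;
    the pollution tier comes from ``site_tiers`` when given, else
    "unknown".
    """
    if not records:
        raise ValueError("pivot_to_matrix requires at least one record")
    df = pd.DataFrame(
        {
            "site_id": [r.site_id for r in records],
            "date": [r.timestamp for r in records],
            "parameter": [r.parameter for r in records],
            "value": [r.value for r in records],
        }
    )
    n_dups = int(df.duplicated(subset=["site_id", "date", "parameter"]).sum())
    if n_dups:
        log.info("pivot_to_matrix: averaged %d duplicate observations", n_dups)
    wide = df.pivot_table(index=["site_id", "date"], columns="parameter",
                          values="value", aggfunc="mean")
    wide = wide.reindex(columns=list(PARAMETERS)).sort_index()
    wide = wide.reset_index()
    meta = pd.DataFrame(
        {
            "site_id": wide["site_id"],
            "date": wide["date"],
            "season": [season_of(d.month) for d in wide["date"]],
            "period": [period_of(d, boundaries) for d in wide["date"]],
            "tier": [
                (site_tiers or {}).get(s, "unknown") for s in wide["site_id"]
            ],
        }
    )
    values = wide[list(PARAMETERS)].astype(float)
    values.index = meta.index = pd.RangeIndex(len(wide))
    return WaterQualityMatrix(values, meta)


def write_wide_csv(matrix: WaterQualityMatrix, path) -> None:
    out = pd.concat([matrix.meta[["site_id", "date"]], matrix.values], axis=1)
    out.to_csv(path, index=False)


def classify_tcb(tcb: float, rules: ThresholdRuleSet | None = None) -> str:
    """Coliform pollution band of a TCB count (MPN/100 mL)."""
    rules = rules or ThresholdRuleSet()
    if tcb < 0:
        raise ValueError("TCB must be non-negative")
    for edge, label in zip(rules.tcb_edges, rules.tcb_labels):
        if tcb <= edge:
            return label
    return rules.tcb_labels[-1]


@dataclass(frozen=True)
class TrophicAssessment:
    tp_eutrophic: bool
    tn_eutrophic: bool
    chl_eutrophic: bool
    tn_tp_ratio: float | None  # mass ratio, common ug/L basis; None if TP == 0
    limitation: str            # "P-limited" | "indeterminate/co-limited" | "undefined"


def classify_trophic_and_limitation(
    tp: float, tn: float, chl: float, rules: ThresholdRuleSet | None = None
) -> TrophicAssessment:
    """Trophic-state flags plus nutrient-limitation call.

    ``tp`` in ug/L, ``tn`` in mg/L, ``chl`` in ug/L. The TN/TP mass
    ratio is formed after converting TN to ug/L; ratios above the
    P-limitation cutoff (default 20) indicate phosphorus-limited algal
    growth, the regime reported for impounded reaches.
    """
    rules = rules or ThresholdRuleSet()
    if min(tp, tn, chl) < 0:
        raise ValueError("concentrations must be non-negative")
    if tp == 0:
        ratio: float | None = None
        limitation = "undefined"
        log.warning("TN/TP ratio undefined: TP is zero")
    else:
        ratio = (tn * 1000.0) / tp
        limitation = ("P-limited" if ratio > rules.tn_tp_p_limit
                      else "indeterminate/co-limited")
    return TrophicAssessment(
        tp_eutrophic=tp > rules.tp_eutrophic,
        tn_eutrophic=tn > rules.tn_eutrophic,
        chl_eutrophic=chl > rules.chl_eutrophic,
        tn_tp_ratio=ratio,
        limitation=limitation,
    )
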