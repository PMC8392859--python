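"""Synthetic monitoring-data generator with known ground truth.

Emulates a monitored river basin: 16 sites in three pollution tiers
(highly / moderately / less polluted), monthly sampling over 15 years,
and concentrations driven by a non-negative 3-source factor structure —
a point-source signal (sewage-treatment-plant effluent, heavy in
BOD/COD/TP/TN/CHL-a), a diffuse agriculture/livestock signal (heavy in
TP/TN/TCB/BOD) and a background/ionic signal (heavy in EC and DO).
On top of the clean mixture G_true @ F_true the generator applies
monsoon-season dilution/enrichment multipliers (nutrients and ions are
diluted by high summer flow while suspended solids and coliforms are
enriched by runoff), slow linear annual trends (organics and
chlorophyll drifting up, nutrients and BOD down, the impoundment-era
pattern), and multiplicative lognormal noise, which preserves the
non-negativity the receptor model requires.

pH is simulated outside the factor model as a bounded variable around
7-8.5; it participates in WQI / PCA / DA but not in receptor-model
fixtures.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import PARAMETERS, MonitoringRecord

#: Parameters driven by the factor model (all except pH), in order.
FACTOR_PARAMETERS: tuple[str, ...] = tuple(p for p in PARAMETERS if p != "pH")

SOURCE_NAMES = ("STP point source", "agriculture/livestock", "background/ionic")

# rows: sources; columns: FACTOR_PARAMETERS
#                 WT    DO     EC    TSS    TP    TN   BOD   COD  CHL-a    TCB
_F_TRUE_DEFAULT = np.array([
    [6.0,  2.0, 120.0,  6.0, 180.0, 3.0,  3.0,  3.5,  18.0,  2000.0],   # STP
    [4.0,  1.0,  60.0,  4.0, 120.0, 2.0,  1.5,  1.2,   5.0, 12000.0],   # agri
    [8.0,  7.0, 280.0,  3.0,  20.0, 0.8,  0.5,  1.0,   4.0,   500.0],   # background
])

#: Mean source activity per tier (STP, agriculture, background).
_TIER_ACTIVITY_DEFAULT = {
    "HP": (2.0, 1.0, 1.0),
    "MP": (0.8, 0.8, 1.0),
    "LP": (0.25, 0.5, 1.0),
}


@dataclass
class GeneratorConfig:
    """Study-condition defaults for the synthetic basin.

    16 sites split 2/5/9 into highly/moderately/less polluted tiers,
    monthly samples over 15 years; monsoon multipliers dilute TP/TN/EC
    (x0.7) and enrich TSS (x2.0) and TCB (x1.5); annual trend slopes
    (relative change per year) push COD and CHL-a up and TP, TN and BOD
    down; sampling noise is multiplicative lognormal with coefficient
    of variation ``noise_cv``.
    """

    n_sites: int = 16
    tier_counts: tuple[int, int, int] = (2, 5, 9)   # HP, MP, LP
    years: int = 15
    start_year: int = 2005
    profiles: np.ndarray = field(
        default_factory=lambda: _F_TRUE_DEFAULT.copy())
    tier_activity: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_TIER_ACTIVITY_DEFAULT))
    activity_cv: float = 0.3        # per-sample lognormal spread of activities
    seasonal_multipliers: dict[str, float] = field(
        default_factory=lambda: {"TP": 0.7, "TN": 0.7, "EC": 0.7,
                                 "TSS": 2.0, "TCB": 1.5})
    trend_slopes: dict[str, float] = field(
        default_factory=lambda: {"COD": 0.02, "CHL-a": 0.02,
                                 "TP": -0.03, "TN": -0.02, "BOD": -0.02})
    noise_cv: float = 0.2
    ph_mean: float = 7.75
    ph_sd: float = 0.35
    mdl: dict[str, float] | None = None   # optional left-censoring limits
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.years < 1:
            raise ValueError("n_sites and years must be positive")
        if sum(self.tier_counts) != self.n_sites:
            raise ValueError("tier counts must sum to n_sites")
        if np.any(np.asarray(self.profiles) < 0):
            raise ValueError("profile entries must be non-negative")
        if self.profiles.shape != (3, len(FACTOR_PARAMETERS)):
            raise ValueError(
                f"profiles must be 3 x {len(FACTOR_PARAMETERS)}")
        for act in self.tier_activity.values():
            if np.any(np.asarray(act) < 0):
                raise ValueError("activities must be non-negative")
        if any(m <= 0 for m in self.seasonal_multipliers.values()):
            raise ValueError("seasonal multipliers must be positive")
        if self.noise_cv < 0 or self.activity_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")


@dataclass
class GroundTruth:
    G_true: pd.DataFrame            # samples x 3 source activities
    F_true: pd.DataFrame            # 3 x factor parameters
    X_clean: pd.DataFrame           # G_true @ F_true, pre-modulation
    tier_of_site: dict[str, str]
    trend_slopes: dict[str, float]
    seasonal_multipliers: dict[str, float]
    censored: pd.DataFrame | None   # boolean mask where values were censored
    config: GeneratorConfig


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma, size=size)


def generate_dataset(
    config: GeneratorConfig | None = None,
) -> tuple[list[MonitoringRecord], GroundTruth]:
    """Generate a full monitoring dataset plus its ground truth.

    Deterministic under ``config.seed``. Each site x month yields one
    observation of all 11 parameters; censored values (below a supplied
    MDL) are reported at MDL/2 and flagged in the truth object.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    tiers = (["HP"] * cfg.tier_counts[0] + ["MP"] * cfg.tier_counts[1]
             + ["LP"] * cfg.tier_counts[2])
    sites = [f"S{i + 1}" for i in range(cfg.n_sites)]
    tier_of_site = dict(zip(sites, tiers))
    dates = [
        dt.date(cfg.start_year + y, m, 15)
        for y in range(cfg.years) for m in range(1, 13)
    ]
    n_samples = cfg.n_sites * len(dates)
    params = list(FACTOR_PARAMETERS)

    index = pd.MultiIndex.from_product([sites, dates], names=["site_id", "date"])
    base_activity = np.array([cfg.tier_activity[tier_of_site[s]] for s in sites])
    G = np.repeat(base_activity, len(dates), axis=0)
    G = G * _lognormal_factor(rng, cfg.activity_cv, G.shape)
    X_clean = G @ cfg.profiles

    # monsoon dilution/enrichment
    months = np.array([d.month for d in dates] * cfg.n_sites)
    monsoon = (months >= 7) & (months <= 8)
    seasonal = np.ones((n_samples, len(params)))
    for pname, mult in cfg.seasonal_multipliers.items():
        j = params.index(pname)
        seasonal[monsoon, j] = mult

    # linear annual trends, centred mid-span so means stay comparable
    year_frac = np.array(
        [(d.year - cfg.start_year) + (d.month - 0.5) / 12.0 for d in dates]
        * cfg.n_sites)
    trend = np.ones((n_samples, len(params)))
    for pname, slope in cfg.trend_slopes.items():
        j = params.index(pname)
        trend[:, j] = np.clip(
            1.0 + slope * (year_frac - cfg.years / 2.0), 0.05, None)

    X = X_clean * seasonal * trend * _lognormal_factor(
        rng, cfg.noise_cv, X_clean.shape)

    ph = np.clip(rng.normal(cfg.ph_mean, cfg.ph_sd, size=n_samples), 0.0, 14.0)

    censored = None
    if cfg.mdl:
        censored = pd.DataFrame(False, index=index, columns=params)
        for pname, limit in cfg.mdl.items():
            j = params.index(pname)
            below = X[:, j] < limit
            X[below, j] = limit / 2.0
            censored.loc[:, pname] = below

    records: list[MonitoringRecord] = []
    for row, (site, date) in enumerate(index):
        records.append(MonitoringRecord(site, date, "pH", float(ph[row])))
        for j, pname in enumerate(params):
            records.append(MonitoringRecord(site, date, pname, float(X[row, j])))

    truth = GroundTruth(
        G_true=pd.DataFrame(G, index=index, columns=list(SOURCE_NAMES)),
        F_true=pd.DataFrame(cfg.profiles, index=list(SOURCE_NAMES),
                            columns=params),
        X_clean=pd.DataFrame(X_clean, index=index, columns=params),
        tier_of_site=tier_of_site,
        trend_slopes=dict(cfg.trend_slopes),
        seasonal_multipliers=dict(cfg.seasonal_multipliers),
        censored=censored,
        config=cfg,
    )
    return records, truth


def make_fixture_suite(seed: int = 0) -> dict[str, tuple[list[MonitoringRecord], GroundTruth]]:
    """Named small datasets exercising each downstream stage.

    - "tiny": 2 sites x 12 months, defaults otherwise.
    - "separated-tiers": 9 sites in three well-separated tiers (x3
      overall-concentration steps, low noise, no modulation) so
      Bray-Curtis clustering at the 60% similarity cut and discriminant
      analysis recover the tiers.
    - "trended": strong monotone drifts (8%/yr) with low noise and no
      seasonality, for trend-test recovery.
    - "rank3-noiseless": exact 3-source factorization (no noise or
      modulation) on which the receptor model reaches Q ~ 0.
    """
    fixtures: dict[str, tuple[list[MonitoringRecord], GroundTruth]] = {}
    fixtures["tiny"] = generate_dataset(GeneratorConfig(
        n_sites=2, tier_counts=(1, 1, 0), years=1, seed=seed))
    fixtures["separated-tiers"] = generate_dataset(GeneratorConfig(
        n_sites=9, tier_counts=(3, 3, 3), years=3,
        tier_activity={"HP": (4.5, 4.5, 4.5), "MP": (1.5, 1.5, 1.5),
                       "LP": (0.5, 0.5, 0.5)},
        activity_cv=0.1, noise_cv=0.05,
        seasonal_multipliers={}, trend_slopes={}, seed=seed + 1))
    fixtures["trended"] = generate_dataset(GeneratorConfig(
        n_sites=2, tier_counts=(1, 1, 0), years=5,
        trend_slopes={"COD": 0.08, "CHL-a": 0.08, "TP": -0.08,
                      "TN": -0.08, "BOD": -0.08},
        activity_cv=0.05, noise_cv=0.05, seasonal_multipliers={},
        seed=seed + 2))
    fixtures["rank3-noiseless"] = generate_dataset(GeneratorConfig(
        n_sites=4, tier_counts=(1, 2, 1), years=2,
        activity_cv=0.3, noise_cv=0.0, seasonal_multipliers={},
        trend_slopes={}, seed=seed + 3))
    return fixtures


def write_truth(truth: GroundTruth, outdir) -> None:
    """Write ground-truth matrices as CSV plus a JSON manifest."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth.G_true.to_csv(out / "G_true.csv")
    truth.F_true.to_csv(out / "F_true.csv")
    cfg = dataclasses.asdict(truth.config)
    cfg["profiles"] = truth.config.profiles.tolist()
    manifest = {
        "seed": truth.config.seed,
        "config": cfg,
        "tiers": truth.tier_of_site,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
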