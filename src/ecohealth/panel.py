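"""Synthetic region × year panels for the forecasting workflow.

Real applications of this pipeline use provincial statistical-yearbook
panels: per region-year, the raw inputs/outputs needed for an eco-efficiency
DEA stage (labor, capital stock, energy use; GDP as the desirable output;
SO2, wastewater and solid waste as undesirable outputs), six socio-economic
control covariates, and five hospital-activity outcome series (visits to
hospitals, outpatients with emergency treatment, inpatients, health
examinations, patients discharged).  Such panels are not freely
redistributable, so this module generates seeded surrogates with the same
statistical structure: a balanced panel with smooth region-heterogeneous
trends, a known (configurable, optionally nonlinear) dependence of every
outcome on eco-efficiency and the controls, and multiplicative relative
noise.  The noiseless generating values are recorded so downstream stages
can be tested against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEA_INPUT_COLUMNS = ("labor", "capital", "energy")
DEA_GOOD_COLUMNS = ("gdp",)
DEA_BAD_COLUMNS = ("so2", "wastewater", "solid_waste")
CONTROL_COLUMNS = (
    "gdp_per_capita",
    "urbanization",
    "pop_density",
    "medical_personnel",
    "licensed_doctors",
    "health_institutions",
)
OUTCOME_COLUMNS = ("vth", "owet", "ni", "nohe", "pd")
REE_COLUMN = "ree"

_ALL_VALUE_COLUMNS = (
    DEA_INPUT_COLUMNS + DEA_GOOD_COLUMNS + DEA_BAD_COLUMNS + CONTROL_COLUMNS + OUTCOME_COLUMNS
)


class PanelConfigError(ValueError):
    """Raised when a panel configuration violates its invariants."""


@dataclass(frozen=True)
class PanelConfig:
    """Configuration of the synthetic panel generator.

    Parameters
    ----------
    n_regions, n_years:
        Panel dimensions.  Defaults match the provincial study design this
        pipeline targets: 30 regions observed over 15 years.
    start_year:
        First calendar year of the panel.
    noise_sd:
        Standard deviation of the multiplicative relative noise applied to
        the outcomes, ``y = f(ree, controls) * (1 + noise_sd * eps)``.
    link:
        Shape of the outcome-on-predictor dependence: ``"nonlinear"``
        (monotone saturating in eco-efficiency, the default) or
        ``"linear"``.
    control_strength:
        Scale of the control-covariate effects on the outcomes.  Zero makes
        every outcome a function of eco-efficiency alone, which is the
        configuration used for single-predictor recovery tests.
    seed:
        RNG seed; regeneration with the same seed is bit-identical.
    """

    n_regions: int = 30
    n_years: int = 15
    start_year: int = 2002
    noise_sd: float = 0.05
    link: str = "nonlinear"
    control_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise PanelConfigError(f"n_regions must be >= 2, got {self.n_regions}")
        if self.n_years < 4:
            raise PanelConfigError(f"n_years must be >= 4, got {self.n_years}")
        if not np.isfinite(self.noise_sd) or self.noise_sd < 0:
            raise PanelConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.link not in ("linear", "nonlinear"):
            raise PanelConfigError(f"link must be 'linear' or 'nonlinear', got {self.link!r}")

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.start_year + self.n_years))


@dataclass
class PanelDataset:
    """A balanced long-format panel.

    ``data`` holds one row per (region, year) with the DEA columns, the six
    controls, the eco-efficiency column ``ree`` (NaN until the DEA stage or
    the generator fills it) and the five outcomes.  ``truth`` optionally
    records the noiseless outcome values of the generating process, and
    ``efficient_truth`` records constructed frontier membership for DEA
    fixtures.
    """

    data: pd.DataFrame
    truth: pd.DataFrame | None = None
    efficient_truth: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def regions(self) -> list[str]:
        return sorted(self.data["region"].unique().tolist())

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique().tolist())

    def validate(self) -> None:
        df = self.data
        for col in ("region", "year"):
            if col not in df.columns:
                raise PanelConfigError(f"panel is missing the {col!r} column")
        counts = df.groupby(["region", "year"]).size()
        if (counts != 1).any():
            raise PanelConfigError("panel has duplicated (region, year) rows")
        n_regions = df["region"].nunique()
        n_years = df["year"].nunique()
        if len(df) != n_regions * n_years:
            raise PanelConfigError(
                f"panel is unbalanced: {len(df)} rows for "
                f"{n_regions} regions x {n_years} years"
            )
        for col in _ALL_VALUE_COLUMNS:
            if col in df.columns:
                vals = df[col].to_numpy(dtype=float)
                if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
                    raise PanelConfigError(f"column {col!r} must be strictly positive and finite")

    def region_block(self, region: str) -> pd.DataFrame:
        """Rows of one region, sorted by year."""
        block = self.data[self.data["region"] == region].sort_values("year")
        if block.empty:
            raise KeyError(f"region {region!r} not in panel")
        return block

    def with_ree(self, ree: pd.Series) -> "PanelDataset":
        """Return a copy whose ``ree`` column is replaced by ``ree`` (aligned on index)."""
        df = self.data.copy()
        df[REE_COLUMN] = ree
        return PanelDataset(data=df, truth=self.truth, efficient_truth=self.efficient_truth)

    # -- plain-text I/O -----------------------------------------------------

    def to_csv(self, path) -> None:
        """Write the panel (plus truth/frontier columns when present) as UTF-8 CSV."""
        df = self.data.copy()
        if self.truth is not None:
            for col in OUTCOME_COLUMNS:
                df[f"truth_{col}"] = self.truth[col].to_numpy()
        if self.efficient_truth is not None:
            df["efficient_truth"] = self.efficient_truth.astype(int).to_numpy()
        df.to_csv(path, index=False, encoding="utf-8")

    @classmethod
    def from_csv(cls, path) -> "PanelDataset":
        df = pd.read_csv(path, encoding="utf-8")
        truth_cols = [c for c in df.columns if c.startswith("truth_")]
        truth = None
        if truth_cols:
            truth = df[truth_cols].rename(columns=lambda c: c[len("truth_"):])
            df = df.drop(columns=truth_cols)
        efficient = None
        if "efficient_truth" in df.columns:
            efficient = df["efficient_truth"].astype(bool)
            df = df.drop(columns=["efficient_truth"])
        return cls(data=df, truth=truth, efficient_truth=efficient)


def _smooth_series(rng: np.random.Generator, t: np.ndarray, base: float,
                   growth: float, wobble: float) -> np.ndarray:
    """A strictly positive smooth trend: exponential growth plus a low-frequency wave."""
    freq = rng.uniform(0.5, 1.5)
    phase = rng.uniform(0, 2 * np.pi)
    series = base * np.exp(growth * t) * (1.0 + wobble * np.sin(2 * np.pi * freq * t + phase))
    return np.maximum(series, 1e-6 * base)


def _ree_trajectory(rng: np.random.Generator, t: np.ndarray) -> np.ndarray:
    """Smooth eco-efficiency path in (0, 1).

    A mild trend plus an oscillation; the final years stay inside the range
    visited earlier, which mirrors the saturating efficiency paths seen in
    regional data and keeps out-of-sample predictor values on the support of
    the training years.
    """
    base = rng.uniform(0.30, 0.70)
    amp = rng.uniform(0.05, 0.15)
    trend = rng.uniform(-0.05, 0.15)
    freq = rng.uniform(0.8, 1.6)
    phase = rng.uniform(0, 2 * np.pi)
    ree = base + trend * t + amp * np.sin(2 * np.pi * freq * t + phase)
    return np.clip(ree, 0.05, 0.99)


def _saturating(ree: np.ndarray) -> np.ndarray:
    """Monotone saturating transform of eco-efficiency used by the nonlinear link."""
    return ree / (0.3 + ree)


# Rough magnitudes for the five outcomes, loosely matched to the units the
# field reports in (1e8 visits, 1e4 persons, 1e4 examinations ...).  They fix
# the scale only; the dynamics come from the link function.
_OUTCOME_BASE_RANGES = {
    "vth": (0.5, 3.0),
    "owet": (0.3, 2.0),
    "ni": (50.0, 300.0),
    "nohe": (100.0, 1000.0),
    "pd": (50.0, 300.0),
}

_CONTROL_BASE_RANGES = {
    "gdp_per_capita": (1.0, 8.0),      # 1e4 yuan
    "urbanization": (0.30, 0.75),      # fraction
    "pop_density": (50.0, 1000.0),     # persons / km^2
    "medical_personnel": (10.0, 80.0),  # 1e4 persons
    "licensed_doctors": (5.0, 40.0),    # 1e4 persons
    "health_institutions": (0.5, 10.0),  # 1e4 institutions
}

_DEA_BASE_RANGES = {
    "labor": (200.0, 3000.0),      # 1e4 persons
    "capital": (1000.0, 30000.0),  # 1e8 yuan
    "energy": (500.0, 10000.0),    # 1e4 tce
    "gdp": (1000.0, 50000.0),      # 1e8 yuan
    "so2": (10.0, 200.0),          # 1e4 tons
    "wastewater": (5000.0, 300000.0),  # 1e4 tons
    "solid_waste": (500.0, 30000.0),   # 1e4 tons
}


def generate_panel(config: PanelConfig) -> PanelDataset:
    """Generate a balanced synthetic panel with known outcome-generating truth.

    Every region draws its own intercepts, slopes and trend parameters from
    seeded distributions, so the panel is heterogeneous across regions in
    the way per-region model fitting assumes.  Outcomes are
    ``f_region(ree, controls) * (1 + noise_sd * eps)`` with standard-normal
    ``eps`` (truncated at four standard deviations so values stay positive);
    the noiseless values are recorded in ``truth``.
    """
    rng = np.random.default_rng(config.seed)
    years = np.asarray(config.years)
    t = (years - years[0]) / (years[-1] - years[0])

    rows: list[dict] = []
    truth_rows: list[dict] = []
    for p in range(config.n_regions):
        region = f"R{p + 1:02d}"
        ree = _ree_trajectory(rng, t)

        # Controls mix a mild growth trend with a dominant low-frequency
        # oscillation so late-sample values stay on the support of earlier
        # years; a pure growth trend would put every holdout year outside
        # the training range and make the dependence unrecoverable by any
        # kernel method.
        controls = {}
        for name in CONTROL_COLUMNS:
            lo, hi = _CONTROL_BASE_RANGES[name]
            base = rng.uniform(lo, hi)
            growth = rng.uniform(0.0, 0.25)
            if name == "urbanization":
                # fractions saturate instead of growing exponentially
                wave = rng.uniform(0.03, 0.10) * np.sin(
                    2 * np.pi * rng.uniform(0.8, 1.6) * t + rng.uniform(0, 2 * np.pi)
                )
                series = np.clip(base + rng.uniform(0.02, 0.12) * t + wave, 0.05, 0.95)
            else:
                series = _smooth_series(rng, t, base, growth, wobble=rng.uniform(0.08, 0.18))
            controls[name] = series

        dea = {}
        for name in _DEA_BASE_RANGES:
            lo, hi = _DEA_BASE_RANGES[name]
            base = rng.uniform(lo, hi)
            growth = rng.uniform(0.1, 0.7) if name == "gdp" else rng.uniform(0.0, 0.5)
            dea[name] = _smooth_series(rng, t, base, growth, wobble=rng.uniform(0.0, 0.05))

        # region-specific outcome models on standardized control scales
        zcontrols = {}
        for name, series in controls.items():
            sd = series.std()
            zcontrols[name] = (series - series.mean()) / (sd if sd > 0 else 1.0)

        outcomes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name in OUTCOME_COLUMNS:
            lo, hi = _OUTCOME_BASE_RANGES[name]
            scale = rng.uniform(lo, hi)
            beta_ree = rng.uniform(0.6, 1.4)
            gammas = rng.normal(0.0, 0.25, size=len(CONTROL_COLUMNS))
            if config.link == "nonlinear":
                g = beta_ree * _saturating(ree)
            else:
                g = beta_ree * ree
            g = g + config.control_strength * sum(
                gam * zcontrols[c] for gam, c in zip(gammas, CONTROL_COLUMNS)
            )
            g = g - g.mean()  # center so `scale` sets the level
            y_true = scale * np.exp(0.5 * g)
            eps = np.clip(rng.standard_normal(len(years)), -4.0, 4.0)
            y_obs = y_true * (1.0 + config.noise_sd * eps)
            outcomes[name] = (y_true, y_obs)

        for i, year in enumerate(years):
            row = {"region": region, "year": int(year), REE_COLUMN: ree[i]}
            for name in _DEA_BASE_RANGES:
                row[name] = dea[name][i]
            for name in CONTROL_COLUMNS:
                row[name] = controls[name][i]
            truth_row = {"region": region, "year": int(year)}
            for name in OUTCOME_COLUMNS:
                y_true, y_obs = outcomes[name]
                row[name] = y_obs[i]
                truth_row[name] = y_true[i]
            rows.append(row)
            truth_rows.append(truth_row)

    data = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    column_order = (
        ["region", "year"]
        + list(DEA_INPUT_COLUMNS)
        + list(DEA_GOOD_COLUMNS)
        + list(DEA_BAD_COLUMNS)
        + list(CONTROL_COLUMNS)
        + [REE_COLUMN]
        + list(OUTCOME_COLUMNS)
    )
    data = data[column_order]
    return PanelDataset(data=data, truth=truth)


def generate_dea_frontier_panel(config: PanelConfig, n_efficient: int) -> PanelDataset:
    """Generate a panel whose DEA frontier membership is known by construction.

    Per year, ``n_efficient`` units lie on a common efficiency ray (each is a
    positive rescaling of one base unit, so no conic or convex combination of
    units can dominate any of them), and the remaining units are copies of
    frontier units with inputs and undesirable outputs inflated by known
    factors, hence dominated.  ``efficient_truth`` records the construction.
    """
    if not 1 <= n_efficient <= config.n_regions:
        raise PanelConfigError(
            f"n_efficient must be in [1, {config.n_regions}], got {n_efficient}"
        )
    rng = np.random.default_rng(config.seed)
    years = config.years

    rows: list[dict] = []
    flags: list[bool] = []
    col_names = list(DEA_INPUT_COLUMNS) + list(DEA_GOOD_COLUMNS) + list(DEA_BAD_COLUMNS)
    for year in years:
        base = {name: rng.uniform(*_DEA_BASE_RANGES[name]) for name in col_names}
        profiles = []
        for p in range(config.n_regions):
            efficient = p < n_efficient
            if efficient:
                s = rng.uniform(0.5, 2.0)
                profile = {name: s * base[name] for name in col_names}
            else:
                donor = profiles[rng.integers(0, n_efficient)]
                factor = rng.uniform(1.2, 2.0)
                profile = dict(donor)
                for name in DEA_INPUT_COLUMNS + DEA_BAD_COLUMNS:
                    profile[name] = donor[name] * factor
            profiles.append(profile)
            row = {"region": f"R{p + 1:02d}", "year": int(year)}
            row.update(profile)
            rows.append(row)
            flags.append(bool(efficient))

    data = pd.DataFrame(rows)
    return PanelDataset(data=data, efficient_truth=pd.Series(flags, index=data.index))
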