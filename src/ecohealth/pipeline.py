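"""Per-region out-of-sample forecasting experiments and error analysis.

For every (region, outcome, model-variant) cell the pipeline standardizes
the predictor columns on the training years, tunes the LS-SVM
hyperparameters with the stochastic search, fits the final model, predicts
a chronological holdout block and reports three accuracy criteria over the
holdout horizon T:

    MPE = (1/T) sum_t (y_t - yhat_t) / y_t          (signed)
    MSE = (1/T) sum_t (y_t - yhat_t)^2
    SDE = sqrt(MSE)

Three nested predictor sets mirror the single-factor / multi-factor
comparison: variant 1 uses eco-efficiency (REE) alone, variant 2 adds GDP
per capita, urbanization and population density, and variant 3 further
adds medical personnel, licensed doctors and health-care institutions —
seven predictors in total.

The stability analysis summarizes how per-year forecast errors shift over
the holdout horizon: for each error criterion the *average degree* is the
mean absolute year-over-year change of the per-region error series and the
*variation degree* is the standard deviation of those absolute changes —
lower values indicate a more stable forecast.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ecohealth.lssvm import KernelParams, fit, predict
from ecohealth.panel import CONTROL_COLUMNS, OUTCOME_COLUMNS, PanelDataset, REE_COLUMN
from ecohealth.search import SearchConfig, search


class MetricsError(ValueError):
    """Raised for invalid metric inputs (length mismatch, zero actuals)."""


@dataclass(frozen=True)
class ModelVariant:
    """One of the three nested predictor sets."""

    id: int
    predictors: tuple[str, ...]

    _SETS = {
        1: (REE_COLUMN,),
        2: (REE_COLUMN, "gdp_per_capita", "urbanization", "pop_density"),
        3: (REE_COLUMN, "gdp_per_capita", "urbanization", "pop_density",
            "medical_personnel", "licensed_doctors", "health_institutions"),
    }

    @classmethod
    def variant(cls, vid: int) -> "ModelVariant":
        if vid not in cls._SETS:
            raise ValueError(f"variant id must be 1, 2 or 3, got {vid}")
        return cls(id=vid, predictors=cls._SETS[vid])


@dataclass(frozen=True)
class ErrorMetrics:
    """MPE/MSE/SDE over a forecast horizon, with the per-year (y, yhat) pairs."""

    mpe: float
    mse: float
    sde: float
    horizon_T: int
    per_year_errors: tuple[tuple[float, float], ...]


def compute_metrics(actuals, predictions, years=None) -> ErrorMetrics:
    """Compute the three accuracy criteria from actual and predicted values.

    MPE is signed (over-prediction of large years can cancel
    under-prediction of small ones); SDE is exactly sqrt(MSE).
    """
    y = np.asarray(actuals, dtype=float)
    yhat = np.asarray(predictions, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or y.size < 1:
        raise MetricsError(f"actuals and predictions must be equal-length 1-D, got {y.shape} vs {yhat.shape}")
    zero = np.nonzero(y == 0)[0]
    if zero.size:
        where = years[zero[0]] if years is not None else f"position {zero[0]}"
        raise MetricsError(f"actual value is zero at {where}; percentage error undefined")
    T = y.size
    diff = y - yhat
    mpe = float(np.sum(diff / y) / T)
    mse = float(np.sum(diff**2) / T)
    return ErrorMetrics(
        mpe=mpe,
        mse=mse,
        sde=float(np.sqrt(mse)),
        horizon_T=T,
        per_year_errors=tuple(zip(y.tolist(), yhat.tolist())),
    )


@dataclass(frozen=True)
class HoldoutSplit:
    """Chronological split: the last ``n_test`` years of each region are held out."""

    n_test: int = 3

    def __post_init__(self) -> None:
        if self.n_test < 1:
            raise ValueError("n_test must be >= 1")

    def split_years(self, years: list[int]) -> tuple[list[int], list[int]]:
        if len(years) - self.n_test < 4:
            raise ValueError(
                f"need >= 4 training years: {len(years)} years, {self.n_test} held out"
            )
        return years[: -self.n_test], years[-self.n_test:]


def _cell_seed(base_seed: int, region: str, outcome: str, variant_id: int) -> int:
    """Stable per-cell seed, independent of panel row order."""
    tag = f"{region}|{outcome}|{variant_id}".encode()
    return int(np.random.SeedSequence([base_seed, zlib.crc32(tag)]).generate_state(1)[0] % (2**31))


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Zero-mean/unit-variance scaling fit on the training block only."""
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mean) / sd, (test - mean) / sd


def run_region(
    panel: PanelDataset,
    region: str,
    outcome: str,
    variant: ModelVariant,
    split: HoldoutSplit | None = None,
    search_cfg: SearchConfig | None = None,
) -> tuple[ErrorMetrics, KernelParams]:
    """Tune, fit and evaluate one (region, outcome, variant) cell.

    Deterministic given the search seed: the per-cell RNG stream is keyed on
    (seed, region, outcome, variant), so panel row order is irrelevant.
    """
    split = split or HoldoutSplit()
    search_cfg = search_cfg or SearchConfig(objective_mode="loocv")
    if outcome not in OUTCOME_COLUMNS:
        raise KeyError(f"unknown outcome {outcome!r}")
    block = panel.region_block(region)
    if block[REE_COLUMN].isna().any():
        raise ValueError(f"region {region!r} has missing eco-efficiency values")
    years = block["year"].tolist()
    train_years, test_years = split.split_years(years)

    X = block[list(variant.predictors)].to_numpy(dtype=float)
    y = block[outcome].to_numpy(dtype=float)
    n_train = len(train_years)
    X_train, X_test = _standardize(X[:n_train], X[n_train:])
    y_train, y_test = y[:n_train], y[n_train:]

    cfg = SearchConfig(
        init_sigma=search_cfg.init_sigma,
        init_gamma=search_cfg.init_gamma,
        epsilon=search_cfg.epsilon,
        max_iter=search_cfg.max_iter,
        seed=_cell_seed(search_cfg.seed, region, outcome, variant.id),
        step_mode=search_cfg.step_mode,
        objective_mode=search_cfg.objective_mode,
        step_scale=search_cfg.step_scale,
        holdout_size=search_cfg.holdout_size,
    )
    try:
        trace = search(X_train, y_train, cfg)
        model = fit(X_train, y_train, trace.final_params)
        yhat = predict(model, X_test)
        metrics = compute_metrics(y_test, yhat, years=test_years)
    except Exception as exc:
        exc.add_note(f"in cell (region={region}, outcome={outcome}, variant={variant.id})")
        raise
    return metrics, trace.final_params


@dataclass
class ExperimentResult:
    """All per-cell metrics of one experiment plus per-(outcome, variant) averages.

    ``cells`` has one row per (region, outcome, variant) with mpe/mse/sde
    and the tuned (sigma, gamma); ``aggregates`` averages the metric columns
    over the regions included in the mean (a designated national-aggregate
    series, when present, is forecast but excluded).  ``metrics`` retains
    the full :class:`ErrorMetrics` per cell for the stability analysis.
    """

    cells: pd.DataFrame
    aggregates: pd.DataFrame
    metrics: dict[tuple[str, str, int], ErrorMetrics]
    variants: list[ModelVariant]
    outcomes: list[str]
    failures: list[str] = field(default_factory=list)


def run_experiment(
    panel: PanelDataset,
    variants: list[ModelVariant] | None = None,
    outcomes: list[str] | None = None,
    split: HoldoutSplit | None = None,
    search_cfg: SearchConfig | None = None,
    national_region: str | None = None,
) -> ExperimentResult:
    """Run the Cartesian product of regions × outcomes × variants.

    Per-cell failures are recorded in ``failures`` and skipped rather than
    aborting the whole experiment.
    """
    variants = variants or [ModelVariant.variant(i) for i in (1, 2, 3)]
    outcomes = list(outcomes or OUTCOME_COLUMNS)
    split = split or HoldoutSplit()
    search_cfg = search_cfg or SearchConfig(objective_mode="loocv")

    rows = []
    metrics: dict[tuple[str, str, int], ErrorMetrics] = {}
    failures: list[str] = []
    for region in panel.regions:
        for outcome in outcomes:
            for variant in variants:
                try:
                    em, params = run_region(panel, region, outcome, variant, split, search_cfg)
                except Exception as exc:
                    failures.append(
                        f"region={region} outcome={outcome} variant={variant.id}: {exc}"
                    )
                    continue
                metrics[(region, outcome, variant.id)] = em
                rows.append(
                    {
                        "region": region,
                        "outcome": outcome,
                        "variant": variant.id,
                        "mpe": em.mpe,
                        "mse": em.mse,
                        "sde": em.sde,
                        "sigma": params.sigma,
                        "gamma": params.gamma,
                    }
                )
    cells = pd.DataFrame(rows)
    agg_src = cells[cells["region"] != national_region] if national_region else cells
    if len(agg_src):
        aggregates = (
            agg_src.groupby(["outcome", "variant"], as_index=False)[["mpe", "mse", "sde"]]
            .mean()
        )
    else:
        aggregates = pd.DataFrame(columns=["outcome", "variant", "mpe", "mse", "sde"])
    return ExperimentResult(
        cells=cells,
        aggregates=aggregates,
        metrics=metrics,
        variants=variants,
        outcomes=outcomes,
        failures=failures,
    )


def _per_year_metric_series(em: ErrorMetrics, metric: str) -> np.ndarray:
    """Single-year values of each error criterion over the holdout horizon."""
    y = np.array([p[0] for p in em.per_year_errors])
    yhat = np.array([p[1] for p in em.per_year_errors])
    diff = y - yhat
    if metric == "mpe":
        return diff / y
    if metric == "mse":
        return diff**2
    if metric == "sde":
        return np.abs(diff)
    raise ValueError(f"unknown metric {metric!r}")


def stability_analysis(result: ExperimentResult) -> pd.DataFrame:
    """Average degree and variation degree of the forecast-error changes.

    For each (outcome, variant, metric) the per-region per-year error series
    is differenced year over year; the average degree is the mean of the
    absolute changes pooled over regions and the variation degree is their
    (population) standard deviation.
    """
    rows = []
    for outcome in result.outcomes:
        for variant in result.variants:
            for metric in ("mpe", "mse", "sde"):
                changes: list[float] = []
                for (region, out, vid), em in result.metrics.items():
                    if out != outcome or vid != variant.id:
                        continue
                    if em.horizon_T < 2:
                        raise ValueError(
                            "stability analysis needs a holdout horizon >= 2"
                        )
                    series = _per_year_metric_series(em, metric)
                    changes.extend(np.abs(np.diff(series)).tolist())
                if not changes:
                    continue
                arr = np.asarray(changes)
                rows.append(
                    {
                        "outcome": outcome,
                        "variant": variant.id,
                        "metric": metric,
                        "average_degree": float(arr.mean()),
                        "variation_degree": float(arr.std()),
                    }
                )
    return pd.DataFrame(rows)
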