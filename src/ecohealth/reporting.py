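"""Table rendering and run manifests.

Rendering mirrors the conventional presentation of per-region forecasting
results: one table per (variant, outcome-group) with a region column, the
MPE/MSE/SDE triple per outcome, and a final Average row.  Rendering is
pure — it never mutates the experiment result — and deterministic, so
re-rendering the same result is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ecohealth.pipeline import ExperimentResult

#: outcome groups per table, matching the two-half presentation of results
TABLE_HALVES = (("vth", "owet", "ni"), ("nohe", "pd"))

_FMT = "{:.5f}"  # 5 decimal places


def _table_frame(result: ExperimentResult, variant_id: int, outcomes) -> pd.DataFrame:
    cells = result.cells
    sub = cells[(cells["variant"] == variant_id) & (cells["outcome"].isin(outcomes))]
    regions = sorted(sub["region"].unique())
    columns = ["region"] + [
        f"{out}_{m}" for out in outcomes for m in ("mpe", "mse", "sde")
    ]
    rows = []
    for region in regions:
        row: dict[str, object] = {"region": region}
        for out in outcomes:
            cell = sub[(sub["region"] == region) & (sub["outcome"] == out)]
            for m in ("mpe", "mse", "sde"):
                row[f"{out}_{m}"] = (
                    _FMT.format(float(cell[m].iloc[0])) if len(cell) else ""
                )
        rows.append(row)
    agg = result.aggregates
    avg_row: dict[str, object] = {"region": "Average"}
    for out in outcomes:
        a = agg[(agg["variant"] == variant_id) & (agg["outcome"] == out)]
        for m in ("mpe", "mse", "sde"):
            avg_row[f"{out}_{m}"] = _FMT.format(float(a[m].iloc[0])) if len(a) else ""
    rows.append(avg_row)
    return pd.DataFrame(rows, columns=columns)


def render_tables(result: ExperimentResult, out_dir, style: str = "csv") -> list[Path]:
    """Write one table file per (variant, outcome-group); returns the paths.

    ``style`` is ``"csv"`` or ``"markdown"``; in markdown the Average row is
    emphasized.  With no regions a header-only table is produced.
    """
    if style not in ("csv", "markdown"):
        raise ValueError(f"style must be 'csv' or 'markdown', got {style!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for variant in result.variants:
        for half, outcomes in enumerate(TABLE_HALVES, start=1):
            group = [o for o in outcomes if o in result.outcomes]
            if not group:
                continue
            frame = _table_frame(result, variant.id, group)
            if len(frame) == 1 and not len(result.cells):
                frame = frame.iloc[0:0]  # header-only when there are no regions
            ext = "csv" if style == "csv" else "md"
            path = out_dir / f"forecast_variant{variant.id}_part{half}.{ext}"
            if style == "csv":
                frame.to_csv(path, index=False, encoding="utf-8")
            else:
                md = frame.copy()
                if len(md):
                    last = md.index[-1]
                    md.loc[last, "region"] = f"**{md.loc[last, 'region']}**"
                path.write_text(md.to_markdown(index=False), encoding="utf-8")
            paths.append(path)
    return paths


def render_stability(stability: pd.DataFrame, path) -> Path:
    """Write the stability table (average/variation degree) as CSV."""
    path = Path(path)
    out = stability.copy()
    for col in ("average_degree", "variation_degree"):
        out[col] = out[col].map(_FMT.format)
    out.to_csv(path, index=False, encoding="utf-8")
    return path


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_text: str
    seeds: dict[str, int]
    outputs: list[str] = field(default_factory=list)
    timings: dict[str, float] = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.config_text.encode("utf-8")).hexdigest()

    def versions(self) -> dict[str, str]:
        import scipy

        from ecohealth import __version__

        return {
            "ecohealth": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        }

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "seeds": self.seeds,
                "versions": self.versions(),
                "timings": self.timings,
                "outputs": self.outputs,
            },
            indent=2,
            sort_keys=True,
        )

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n", encoding="utf-8")
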