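"""Rapidity-of-change (R′) of landscape attributes in factor space.

Each structural or functional entity has coordinates on the retained
factor axes at every observation year.  Its rapidity of change over a
stage window [t0, t1] is the Euclidean displacement divided by the window
length in years:

    R′ = √( Σ_a (x_{a,t1} − x_{a,t0})² ) / (t1 − t0)

Entities strictly above the median R′ of their dimension (structures and
functions taken separately) are "fast" variables, the rest "slow"; the
per-dimension mean R′ summarises a stage's overall dynamism.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .nomenclature import (
    FUNCTION_NAMES,
    LONG_TERM_WINDOW,
    STAGE_WINDOWS,
    STRUCTURE_NAMES,
)


@dataclass(frozen=True)
class StageWindow:
    """A development-stage window [t0, t1]; dt is its length in years."""

    label: str
    t0: int
    t1: int

    def __post_init__(self) -> None:
        if self.t1 <= self.t0:
            raise ValueError(f"window {self.label!r}: t1 must exceed t0")

    @property
    def dt(self) -> int:
        return self.t1 - self.t0


def default_windows(include_long_term: bool = False) -> list[StageWindow]:
    """The canonical stage windows (urbanisation, suburbanisation,
    counter-urbanisation), optionally plus the full long-term cycle."""
    windows = [StageWindow(label, t0, t1) for label, (t0, t1) in STAGE_WINDOWS.items()]
    if include_long_term:
        windows.append(StageWindow("long_term", *LONG_TERM_WINDOW))
    return windows


@dataclass
class RapidityResult:
    """Per-entity R′ by window plus fast/slow labels and dimension averages."""

    values: pd.DataFrame  # columns: entity, dimension, window, rprime
    labels: pd.DataFrame  # columns: entity, dimension, window, label
    averages: pd.DataFrame  # columns: dimension, window, mean_rprime


def rapidity_metric(coords_t0: np.ndarray, coords_t1: np.ndarray, dt: float) -> float:
    """R′ between two coordinate vectors: Euclidean distance over Δt.

    The division by the interval length sits outside the radical, making
    R′ a per-year speed in factor-space units.
    """
    a = np.asarray(coords_t0, dtype=float)
    b = np.asarray(coords_t1, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError(f"coordinate vectors must match and be 1-D, got {a.shape} vs {b.shape}")
    if dt <= 0:
        raise ValueError(f"time interval must be positive, got {dt}")
    return float(np.sqrt(((b - a) ** 2).sum()) / dt)


def load_axis_coordinates(path: str | Path) -> pd.DataFrame:
    """Read a long-format coordinates CSV with columns entity, year, axis, value."""
    df = pd.read_csv(path)
    missing = {"entity", "year", "axis", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: coordinate table missing columns {sorted(missing)}")
    return df


def _pivot(coords: pd.DataFrame) -> pd.DataFrame:
    return coords.pivot_table(index=["entity", "year"], columns="axis", values="value")


def infer_dimension(entity: str) -> str:
    """Classify an entity name as 'structure' or 'function' by the nomenclature."""
    if entity in STRUCTURE_NAMES:
        return "structure"
    if entity in FUNCTION_NAMES:
        return "function"
    raise KeyError(f"entity {entity!r} is neither a known structure nor function")


def stage_table(
    coords: pd.DataFrame,
    windows: list[StageWindow] | None = None,
    dimensions: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-entity R′ for every window.

    ``coords`` is long-format (entity, year, axis, value).  ``dimensions``
    optionally maps entity → dimension name; by default the canonical
    structure/function nomenclature is used.
    """
    windows = windows or default_windows()
    wide = _pivot(coords)
    entities = wide.index.get_level_values("entity").unique()
    years_present = set(wide.index.get_level_values("year").unique())
    rows = []
    for w in windows:
        for y in (w.t0, w.t1):
            if y not in years_present:
                raise ValueError(f"window {w.label!r} needs year {y}, absent from coordinates")
        for e in entities:
            r = rapidity_metric(wide.loc[(e, w.t0)].values, wide.loc[(e, w.t1)].values, w.dt)
            dim = dimensions[e] if dimensions else infer_dimension(e)
            rows.append({"entity": e, "dimension": dim, "window": w.label, "rprime": r})
    return pd.DataFrame(rows)


def fast_slow(values: pd.Series) -> pd.Series:
    """Label entities above their dimension's median R′ as fast, the rest slow.

    Exactly-at-median values are slow (deterministic tie rule).
    """
    if len(values) < 2:
        raise ValueError("fast/slow classification needs at least 2 values")
    med = values.median()
    return pd.Series(np.where(values > med, "fast", "slow"), index=values.index)


def dimension_average(values: pd.DataFrame, dimension: str, window: str) -> float:
    """Mean R′ over one dimension's entities in one window."""
    sel = values[(values["dimension"] == dimension) & (values["window"] == window)]
    if sel.empty:
        raise ValueError(f"no R' values for dimension={dimension!r}, window={window!r}")
    return float(sel["rprime"].mean())


def analyse(
    coords: pd.DataFrame,
    windows: list[StageWindow] | None = None,
    dimensions: dict[str, str] | None = None,
) -> RapidityResult:
    """Full rapidity analysis: per-entity R′, fast/slow labels, stage averages."""
    windows = windows or default_windows(include_long_term=True)
    values = stage_table(coords, windows, dimensions)
    labels = []
    for (dim, win), grp in values.groupby(["dimension", "window"], sort=False):
        lab = fast_slow(grp.set_index("entity")["rprime"])
        for e, l in lab.items():
            labels.append({"entity": e, "dimension": dim, "window": win, "label": l})
    averages = (
        values.groupby(["dimension", "window"], sort=False)["rprime"]
        .mean()
        .rename("mean_rprime")
        .reset_index()
    )
    return RapidityResult(values=values, labels=pd.DataFrame(labels), averages=averages)


def coordinates_from_mfa(result) -> pd.DataFrame:
    """Long-format axis coordinates from an MfaResult (loadings + scores)."""
    rows = []
    for year, df in result.partial_loadings.items():
        for entity, row in df.iterrows():
            for i, v in enumerate(row.values, start=1):
                rows.append({"entity": entity, "year": year, "axis": i, "value": float(v)})
    for year, df in result.partial_scores.items():
        for entity, row in df.iterrows():
            for i, v in enumerate(row.values, start=1):
                rows.append({"entity": entity, "year": year, "axis": i, "value": float(v)})
    return pd.DataFrame(rows)
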