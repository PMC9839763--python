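"""Patch statistics and change-rate tables.

Per (year, land-use class, morphological type) the module counts
8-connected patches, sums their area in hectares and derives the mean
patch size — the quantity that feeds the multi-way factor analysis.  Two
change-rate conventions are provided:

* ``annual_percent_change`` — 100·(v1−v0)/(v0·Δt), a linear rate relative
  to the initial value, the convention behind the per-class core-share
  rates; a compound (geometric) mode is available but not the default.
* ``annual_absolute_change`` — (v1−v0)/Δt in the variable's own unit
  (ha/yr for mean patch size), the convention behind the per-cell rates of
  the mean-patch-size change table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .mspa import MspaSegmentation
from .nomenclature import FUNCTION_NAMES, MSPA_CODES, STRUCTURE_NAMES

_FOOTPRINT8 = np.ones((3, 3), dtype=bool)


def patch_stats(
    seg: MspaSegmentation,
    cell_size: float = 100.0,
    year: int | None = None,
    land_use: str | None = None,
) -> pd.DataFrame:
    """Patch count, total area (ha) and mean patch size per morphological type.

    Patches are 8-connected components within one type.  Absent types get
    count 0 and mean 0.  ``mean_patch_size_ha × patch_count`` always equals
    ``total_area_ha``.
    """
    cell_area_ha = (cell_size / 100.0) ** 2
    rows = []
    for name in STRUCTURE_NAMES:
        mask = seg.types == MSPA_CODES[name]
        _, n = ndimage.label(mask, structure=_FOOTPRINT8)
        total = float(mask.sum()) * cell_area_ha
        rows.append(
            {
                "year": year,
                "land_use": land_use,
                "morphology": name,
                "patch_count": int(n),
                "total_area_ha": total,
                "mean_patch_size_ha": total / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows)


def core_share(seg: MspaSegmentation) -> float:
    """Per cent share of core area in the class's total foreground area."""
    fg = int(seg.foreground.sum())
    if fg == 0:
        raise ValueError("core share undefined on an empty segmentation")
    return 100.0 * float(seg.mask_of("core").sum()) / fg


def annual_percent_change(v0: float, v1: float, dt: float, compound: bool = False) -> float:
    """Per cent change per year between two same-unit values.

    Default is the linear rate relative to the initial value,
    100·(v1−v0)/(v0·Δt); set ``compound=True`` for the geometric rate
    100·((v1/v0)^(1/Δt) − 1).
    """
    if dt <= 0:
        raise ValueError(f"time interval must be positive, got {dt}")
    if v0 <= 0:
        raise ValueError(f"initial value must be positive, got {v0}")
    if compound:
        return 100.0 * ((v1 / v0) ** (1.0 / dt) - 1.0)
    return 100.0 * (v1 - v0) / (v0 * dt)


def annual_absolute_change(v0: float, v1: float, dt: float) -> float:
    """Change per year in the variable's own unit: (v1−v0)/Δt."""
    if dt <= 0:
        raise ValueError(f"time interval must be positive, got {dt}")
    return (v1 - v0) / dt


def build_sf_matrix(stats: pd.DataFrame, year: int) -> pd.DataFrame:
    """Build the 9×7 structure-function table of mean patch size for one year.

    Rows are the nine functional (land-use) classes, columns the seven
    structural types; combinations absent from ``stats`` are 0.
    """
    sub = stats[stats["year"] == year] if "year" in stats else stats
    mat = pd.DataFrame(0.0, index=list(FUNCTION_NAMES), columns=list(STRUCTURE_NAMES))
    for row in sub.itertuples():
        if row.land_use in mat.index and row.morphology in mat.columns:
            mat.loc[row.land_use, row.morphology] = float(row.mean_patch_size_ha)
    mat.index.name = "function"
    mat.columns.name = "structure"
    return mat


def sf_change_table(
    matrices: dict[int, pd.DataFrame],
    windows: list[tuple[str, int, int]],
) -> pd.DataFrame:
    """Annual absolute change (ha/yr) of every structure-function cell per stage.

    ``windows`` is a list of (stage label, start year, end year); both years
    must key into ``matrices``.
    """
    frames = []
    for label, y0, y1 in windows:
        m0, m1 = matrices[y0], matrices[y1]
        rate = (m1 - m0) / float(y1 - y0)
        long = rate.stack().rename("annual_change_ha").reset_index()
        long.insert(0, "stage", label)
        frames.append(long)
    return pd.concat(frames, ignore_index=True)


def share_change_table(
    shares: pd.DataFrame,
    windows: list[tuple[str, int, int]],
    compound: bool = False,
) -> pd.DataFrame:
    """Annual per cent change of per-class core shares for each stage window.

    ``shares`` has one row per land-use class and one column per year
    (integer column labels).  Classes with a zero starting share get NaN
    rather than raising, so a single empty class does not abort a run.
    """
    rows = []
    for label, y0, y1 in windows:
        dt = float(y1 - y0)
        for cls in shares.index:
            v0, v1 = float(shares.loc[cls, y0]), float(shares.loc[cls, y1])
            try:
                rate = annual_percent_change(v0, v1, dt, compound=compound)
            except ValueError:
                rate = float("nan")
            rows.append({"stage": label, "land_use": cls, "percent_per_year": rate})
    return pd.DataFrame(rows)
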