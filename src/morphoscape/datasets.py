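"""Loaders for the packaged reference tables of the Rome 1949-2016 study.

Four small CSVs ship with the package, transcribed from the published
tables of a long-term landscape study of metropolitan Rome:

* per-class core-area shares (%) and their printed annual rates;
* the 9×7 mean-patch-size tables for 1949, 1974, 1999 and 2016;
* the printed annual change (ha/yr) of every mean-patch-size cell;
* the axis-1..3 coordinates of all 16 entities at the four years.

They are inputs (the original rasters were never deposited) and double as
regression fixtures for the statistical modules.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .nomenclature import FUNCTION_NAMES, OBSERVATION_YEARS, STRUCTURE_NAMES


def _read(name: str) -> pd.DataFrame:
    with resources.files("morphoscape.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_core_shares() -> pd.DataFrame:
    """Core-share table: per class, share per year and printed annual rates."""
    return _read("rome_core_share.csv").set_index("function")


def load_mean_patch_size() -> dict[int, pd.DataFrame]:
    """The four 9×7 year tables of mean patch size (ha), functions × structures."""
    long = _read("rome_mean_patch_size.csv")
    out: dict[int, pd.DataFrame] = {}
    for year in OBSERVATION_YEARS:
        sub = long[long["year"] == year]
        mat = sub.pivot_table(index="function", columns="structure",
                              values="mean_patch_size_ha")
        out[year] = mat.reindex(index=list(FUNCTION_NAMES), columns=list(STRUCTURE_NAMES))
    return out


def load_annual_change() -> pd.DataFrame:
    """Printed annual change of mean patch size (ha/yr) per stage/function/structure."""
    return _read("rome_patch_size_change.csv")


def load_axis_coordinates() -> pd.DataFrame:
    """Printed axis coordinates, long format (entity, year, axis, value)."""
    return _read("rome_axis_coordinates.csv")
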