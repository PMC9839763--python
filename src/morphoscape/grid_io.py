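"""Categorical raster I/O, per-class masks and connected-component labelling.

Grids are small integer lattices: 0 marks nodata / outside the study area,
1-9 are land-use codes (:mod:`morphoscape.nomenclature`).  Two on-disk
formats are supported: the ESRI ASCII grid (plain text, fully header-aware)
and single-band TIFF via :mod:`tifffile`, with the cell size and year stored
in the image-description tag.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

_ASCII_HEADER_KEYS = {"ncols", "nrows", "cellsize"}


class GridFormatError(ValueError):
    """Raised when a raster file does not parse under the named standard."""


@dataclass
class LandUseGrid:
    """A categorical land-use raster.

    Parameters
    ----------
    values
        2-D integer array; 0 = nodata/outside, 1-9 = land-use codes.
    cell_size
        Metres per pixel side.  The default of 100 m makes one pixel equal
        one hectare, the usual minimum mapping unit of regional land-use maps.
    year
        Observation-year label, or ``None`` when not part of a time series.
    """

    values: np.ndarray
    cell_size: float = 100.0
    year: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"grid values must be 2-D, got shape {self.values.shape}")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("grid values must be integers")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        bad = (self.values < 0) | (self.values > 9)
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} cell(s) outside the 0-9 nomenclature; "
                "use read_grid() to remap unknown codes to nodata"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_ha(self) -> float:
        """Area of one pixel in hectares."""
        return (self.cell_size / 100.0) ** 2


@dataclass
class BinaryMask:
    """Boolean lattice marking the pixels of one land-use class."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class LabelGrid:
    """Connected-component labelling: 0 = unlabeled, labels run 1..n_labels."""

    values: np.ndarray
    n_labels: int = field(default=0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("label grid must be 2-D")


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def relabel_row_major(labels: np.ndarray) -> np.ndarray:
    """Renumber labels so label k is the k-th component met in row-major scan."""
    flat = labels.ravel()
    seen: dict[int, int] = {}
    order = np.zeros(int(labels.max()) + 1, dtype=labels.dtype)
    for v in flat:
        if v and v not in seen:
            seen[v] = len(seen) + 1
            order[v] = seen[v]
    return order[labels]


def label_components(mask: BinaryMask | np.ndarray, connectivity: int = 8) -> LabelGrid:
    """Label maximal connected components of a boolean mask.

    Labels are assigned in row-major order of each component's first pixel,
    so the result is deterministic and mirror-permutation friendly.
    """
    values = mask.values if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    lab, n = ndimage.label(values, structure=_structure(connectivity))
    if n:
        lab = relabel_row_major(lab)
    return LabelGrid(values=lab, n_labels=int(n))


def class_mask(grid: LandUseGrid, code: int) -> BinaryMask:
    """Binary mask of one land-use class; nodata and all other classes are background."""
    if not (1 <= int(code) <= 9):
        raise ValueError(f"land-use code must be 1-9, got {code}")
    return BinaryMask(values=grid.values == int(code))


# ---------------------------------------------------------------------------
# file formats


def _read_ascii_grid(path: Path) -> tuple[np.ndarray, float]:
    lines = path.read_text().splitlines()
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0][:1].isalpha():
            key = parts[0].lower()
            try:
                header[key] = float(parts[1])
                body_start = i + 1
                continue
            except ValueError:
                pass
        break
    missing = _ASCII_HEADER_KEYS - set(header)
    if missing:
        raise GridFormatError(
            f"{path}: ESRI ASCII grid header missing {sorted(missing)}"
        )
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if "dx" in header or "dy" in header:
        raise GridFormatError(f"{path}: non-square pixels (dx/dy header) not supported")
    body = " ".join(lines[body_start:])
    try:
        data = np.array(body.split(), dtype=float)
    except ValueError as exc:
        raise GridFormatError(f"{path}: unparsable grid body: {exc}") from None
    if data.size != nrows * ncols:
        raise GridFormatError(
            f"{path}: expected {nrows * ncols} values, found {data.size}"
        )
    values = data.reshape(nrows, ncols)
    nodata = header.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, 0, values)
    return values.astype(np.int64), float(header["cellsize"])


def _write_ascii_grid(grid: LandUseGrid, path: Path) -> None:
    h, w = grid.shape
    header = (
        f"ncols {w}\n"
        f"nrows {h}\n"
        f"xllcorner 0.0\n"
        f"yllcorner 0.0\n"
        f"cellsize {grid.cell_size:g}\n"
        f"NODATA_value 0\n"
    )
    body = "\n".join(" ".join(str(int(v)) for v in row) for row in grid.values)
    path.write_text(header + body + "\n")


def _read_tiff(path: Path) -> tuple[np.ndarray, float, int | None]:
    import tifffile

    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            values = page.asarray()
            desc = page.tags.get("ImageDescription")
            meta: dict = {}
            if desc is not None:
                try:
                    meta = json.loads(desc.value)
                except (TypeError, json.JSONDecodeError):
                    meta = {}
    except (tifffile.TiffFileError, FileNotFoundError) as exc:
        raise GridFormatError(f"{path}: unreadable TIFF: {exc}") from None
    if values.ndim == 3:
        values = values[..., 0]  # band 1 only
    cell_size = float(meta.get("cell_size", 100.0))
    year = meta.get("year")
    return values.astype(np.int64), cell_size, year


def _write_tiff(grid: LandUseGrid, path: Path) -> None:
    import tifffile

    meta = {"cell_size": grid.cell_size, "year": grid.year}
    tifffile.imwrite(path, grid.values.astype(np.int32), description=json.dumps(meta))


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in {".asc", ".agr", ".grd", ".txt"}:
        return "ascii_grid"
    if suffix in {".tif", ".tiff"}:
        return "geotiff"
    raise GridFormatError(f"{path}: cannot infer raster format from suffix {suffix!r}")


def read_grid(path: str | Path, fmt: str | None = None, year: int | None = None) -> LandUseGrid:
    """Read a categorical land-use raster.

    Values outside the 0-9 nomenclature are remapped to 0 (nodata) with a
    logged warning, so foreign rasters degrade gracefully rather than fail.
    """
    path = Path(path)
    if not path.exists():
        raise GridFormatError(f"{path}: no such file")
    fmt = _infer_format(path, fmt)
    if fmt == "ascii_grid":
        values, cell_size = _read_ascii_grid(path)
        file_year = None
    elif fmt == "geotiff":
        values, cell_size, file_year = _read_tiff(path)
    else:
        raise GridFormatError(f"unknown format {fmt!r}; expected geotiff or ascii_grid")
    out_of_range = (values < 0) | (values > 9)
    n_bad = int(out_of_range.sum())
    if n_bad:
        logger.warning("%s: %d cell(s) outside the 0-9 nomenclature remapped to nodata", path, n_bad)
        values = np.where(out_of_range, 0, values)
    return LandUseGrid(values=values, cell_size=cell_size, year=year if year is not None else file_year)


def write_grid(grid: LandUseGrid, path: str | Path, fmt: str | None = None) -> Path:
    """Write a grid; the format is inferred from the suffix unless given."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "ascii_grid":
        _write_ascii_grid(grid, path)
    elif fmt == "geotiff":
        _write_tiff(grid, path)
    else:
        raise GridFormatError(f"unknown format {fmt!r}")
    return path
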