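"""Land-use nomenclature, morphological type codes and development-stage windows.

The package works on categorical rasters with a nine-class land-use
nomenclature typical of Mediterranean metropolitan regions (an urban pair
plus seven agro-forest classes), and partitions each class into the seven
morphological types of a morphological spatial pattern analysis (MSPA).
"""

from __future__ import annotations

#: Land-use class codes (raster values). 0 is nodata / outside the study area.
LAND_USE_CODES: dict[str, int] = {
    "built_up": 1,
    "urban_green": 2,
    "arable": 3,
    "crop_mosaic": 4,
    "vineyards": 5,
    "olive_groves": 6,
    "woodland": 7,
    "pastures": 8,
    "wetlands": 9,
}

#: Canonical ordering of the nine functional (land-use) classes.
FUNCTION_NAMES: tuple[str, ...] = tuple(LAND_USE_CODES)

#: Canonical ordering of the seven structural (morphological) types.
STRUCTURE_NAMES: tuple[str, ...] = (
    "core",
    "islet",
    "perforation",
    "edge",
    "loop",
    "bridge",
    "branch",
)

#: Raster codes used when a segmentation is written to disk.
MSPA_CODES: dict[str, int] = {
    "none": 0,
    "core": 1,
    "islet": 2,
    "perforation": 3,
    "edge": 4,
    "loop": 5,
    "bridge": 6,
    "branch": 7,
}

#: City-life-cycle stage windows: label -> (start year, end year).
#: Urbanisation and suburbanisation span 25 years, counter-urbanisation 17.
STAGE_WINDOWS: dict[str, tuple[int, int]] = {
    "urbanisation": (1949, 1974),
    "suburbanisation": (1974, 1999),
    "counter_urbanisation": (1999, 2016),
}

#: The full metropolitan cycle, first to last observation.
LONG_TERM_WINDOW: tuple[int, int] = (1949, 2016)

#: Observation years of the reference four-date series.
OBSERVATION_YEARS: tuple[int, ...] = (1949, 1974, 1999, 2016)


def land_use_name(code: int) -> str:
    """Return the class name for a land-use code 1-9."""
    for name, c in LAND_USE_CODES.items():
        if c == code:
            return name
    raise KeyError(f"unknown land-use code {code!r}; expected 1-9")
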