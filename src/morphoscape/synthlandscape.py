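"""Synthetic four-date land-use series with city-life-cycle growth stages.

The generator emulates the study conditions of a post-war Mediterranean
metropolis observed at four dates: a compact urban nucleus inside a
spatially autocorrelated rural mosaic, followed by three growth stages —

* **compact densification** (t0→t1): the nucleus dilates outward,
  emulating the urbanisation stage;
* **dispersed fringe expansion** (t1→t2): urban seeds sprout in a fringe
  ring around the nucleus and grow one or two steps, fragmenting the
  rural classes (suburbanisation);
* **diffuse sprinkle** (t2→t3): isolated single urban pixels appear in
  the remaining rural matrix (counter-urbanisation sprawl).

The rural mosaic is a neutral-landscape model: independent smoothed
uniform-noise fields ranked and thresholded to hit target class
proportions.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid_io import LandUseGrid
from .nomenclature import LAND_USE_CODES, OBSERVATION_YEARS

_FOOTPRINT8 = np.ones((3, 3), dtype=bool)

#: Default class proportions at t0, loosely modelled on an arable-dominant
#: Mediterranean metropolitan region with ~7% initial urban cover.
DEFAULT_PROPORTIONS: dict[str, float] = {
    "built_up": 0.07,
    "urban_green": 0.02,
    "arable": 0.35,
    "crop_mosaic": 0.08,
    "vineyards": 0.07,
    "olive_groves": 0.04,
    "woodland": 0.20,
    "pastures": 0.15,
    "wetlands": 0.02,
}

#: Classes that may be consumed by urban growth (everything but built-up).
RURAL_CODES = tuple(code for name, code in LAND_USE_CODES.items() if name != "built_up")


@dataclass
class SynthConfig:
    """Generator settings.

    Rates are pixel budgets per stage (expected urban pixels added); the
    defaults scale the printed built-up shares of the reference study
    (6.6 → 15.9 → 25.9 → 27.6 % of the study area) onto a 256×256 grid.
    """

    grid_size: int = 256
    cell_size: float = 100.0
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    densify_rate: int = 6000
    disperse_rate: int = 6500
    sprinkle_rate: int = 1100
    smoothing_scale: float = 4.0
    seed: int = 0
    years: tuple[int, int, int, int] = OBSERVATION_YEARS

    @classmethod
    def scaled(cls, grid_size: int, seed: int = 0, **overrides) -> "SynthConfig":
        """Default config with the stage pixel budgets scaled to the grid area,
        preserving the reference built-up share trajectory at any size."""
        ratio = (grid_size / cls.grid_size) ** 2
        budgets = {
            name: max(1, int(round(getattr(cls, name) * ratio)))
            for name in ("densify_rate", "disperse_rate", "sprinkle_rate")
            if name not in overrides
        }
        return cls(grid_size=grid_size, seed=seed, **budgets, **overrides)

    def __post_init__(self) -> None:
        if self.grid_size < 32:
            raise ValueError(f"grid_size must be >= 32, got {self.grid_size}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {total}")
        if min(self.class_proportions.values()) < 0:
            raise ValueError("class proportions must be non-negative")
        for name in ("densify_rate", "disperse_rate", "sprinkle_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        unknown = set(self.class_proportions) - set(LAND_USE_CODES)
        if unknown:
            raise ValueError(f"unknown class names in proportions: {sorted(unknown)}")


def _nucleus(size: int, n_pixels: int) -> np.ndarray:
    """Euclidean disk of ~n_pixels centred on the grid."""
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    d2 = (yy - c) ** 2 + (xx - c) ** 2
    order = np.argsort(d2.ravel(), kind="stable")
    disk = np.zeros(size * size, dtype=bool)
    disk[order[:n_pixels]] = True
    return disk.reshape(size, size)


def _rural_mosaic(
    rng: np.random.Generator,
    unassigned: np.ndarray,
    targets: dict[str, int],
    smoothing_scale: float,
) -> np.ndarray:
    """Fill non-urban pixels with autocorrelated class patches.

    One smoothed uniform-noise field per class; classes claim their target
    pixel counts greedily by field rank, the last class takes the rest.
    """
    size = unassigned.shape[0]
    values = np.zeros(unassigned.shape, dtype=np.int64)
    names = [n for n in targets if targets[n] > 0]
    free = unassigned.copy()
    for idx, name in enumerate(names):
        noise = rng.uniform(size=(size, size))
        fld = ndimage.gaussian_filter(noise, sigma=smoothing_scale, mode="wrap")
        if idx == len(names) - 1:
            values[free] = LAND_USE_CODES[name]
            break
        score = np.where(free, fld, -np.inf).ravel()
        take = np.argsort(score, kind="stable")[::-1][: min(targets[name], int(free.sum()))]
        mask = np.zeros(size * size, dtype=bool)
        mask[take] = True
        mask &= free.ravel()
        values.ravel()[mask] = LAND_USE_CODES[name]
        free &= ~mask.reshape(size, size)
    return values


def _grow_compact(values: np.ndarray, budget: int) -> np.ndarray:
    """Convert the `budget` rural pixels closest to the urban mass (then
    row-major) to built-up — morphological dilation with a partial last ring."""
    if budget == 0:
        return values
    urban = values == LAND_USE_CODES["built_up"]
    rural = ~urban & (values > 0)
    if int(rural.sum()) < budget:
        raise ValueError("densify_rate exceeds the available rural area")
    dist = ndimage.distance_transform_cdt(~urban, metric="chessboard")
    flat_idx = np.arange(values.size)
    candidates = flat_idx[rural.ravel()]
    order = np.lexsort((candidates, dist.ravel()[candidates]))
    chosen = candidates[order[:budget]]
    out = values.copy()
    out.ravel()[chosen] = LAND_USE_CODES["built_up"]
    return out


def _fringe_ring(values: np.ndarray) -> np.ndarray:
    """Chebyshev ring [r+2, 2.5r] around the urban centroid (r = urban
    'radius' from its pixel count)."""
    urban = values == LAND_USE_CODES["built_up"]
    n = int(urban.sum())
    r = max(int(np.sqrt(n / np.pi)), 2)
    ci, cj = (x.mean() for x in np.nonzero(urban))
    yy, xx = np.mgrid[0: values.shape[0], 0: values.shape[1]]
    cheb = np.maximum(np.abs(yy - ci), np.abs(xx - cj))
    return (cheb >= r + 2) & (cheb <= 2.5 * r)


def _grow_dispersed(values: np.ndarray, budget: int, rng: np.random.Generator) -> np.ndarray:
    """Plant discontinuous settlement patches in the fringe ring.

    Each seed becomes a small ragged cluster (the seed plus a random subset
    of its 1-2-step Chebyshev neighbourhood, grown over one or two rings):
    medium-density expansion whose patches are mostly too small and
    irregular to form cores, fragmenting the rural classes they consume.
    """
    if budget == 0:
        return values
    out = values.copy()
    ring = _fringe_ring(values)
    added = 0
    attempts = 0
    size = values.shape[0]
    while added < budget:
        rural = (out > 0) & (out != LAND_USE_CODES["built_up"])
        pool = np.nonzero((ring & rural).ravel())[0]
        if pool.size == 0 or attempts > 10 * budget:
            if added == 0:
                raise ValueError("disperse_rate exceeds the available fringe rural area")
            break
        attempts += 1
        pos = int(rng.choice(pool))
        i, j = divmod(pos, size)
        radius = int(rng.integers(1, 3))
        ii, jj = np.mgrid[
            max(0, i - radius): min(size, i + radius + 1),
            max(0, j - radius): min(size, j + radius + 1),
        ]
        cand = np.stack([ii.ravel(), jj.ravel()], axis=1)
        cand = cand[(cand[:, 0] != i) | (cand[:, 1] != j)]
        cand = cand[rural[cand[:, 0], cand[:, 1]]]
        rng.shuffle(cand, axis=0)
        # keep the cluster under the full neighbourhood so it stays coreless
        k = int(rng.integers(2, max(3, int(0.7 * len(cand)) + 1))) if len(cand) else 0
        k = min(k, len(cand), max(budget - added - 1, 0))
        out[i, j] = LAND_USE_CODES["built_up"]
        added += 1
        if k:
            sel = cand[:k]
            out[sel[:, 0], sel[:, 1]] = LAND_USE_CODES["built_up"]
            added += k
    return out


def _sprinkle(values: np.ndarray, budget: int, rng: np.random.Generator) -> np.ndarray:
    """Add isolated single urban pixels (no 8-adjacency to existing urban)."""
    if budget == 0:
        return values
    out = values.copy()
    added = 0
    attempts = 0
    size = values.shape[0]
    while added < budget and attempts < 50 * budget:
        attempts += 1
        urban = out == LAND_USE_CODES["built_up"]
        near_urban = ndimage.binary_dilation(urban, structure=_FOOTPRINT8)
        pool = np.nonzero(((out > 0) & ~urban & ~near_urban).ravel())[0]
        if pool.size == 0:
            break
        take = rng.choice(pool, size=min(budget - added, 64), replace=False)
        # keep a mutually non-adjacent subset of this draw
        keep = []
        occupied: set[tuple[int, int]] = set()
        for t in take:
            i, j = divmod(int(t), size)
            if all((i + di, j + dj) not in occupied for di in (-1, 0, 1) for dj in (-1, 0, 1)):
                keep.append(t)
                occupied.add((i, j))
        out.ravel()[np.asarray(keep, dtype=int)] = LAND_USE_CODES["built_up"]
        added += len(keep)
    if added == 0 and budget > 0:
        raise ValueError("sprinkle_rate exceeds the available isolated rural area")
    return out


def generate_series(config: SynthConfig | None = None) -> list[LandUseGrid]:
    """Generate the four-date series t0..t3; fully reproducible from the seed."""
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    size = config.grid_size
    total = size * size

    targets = {n: int(round(p * total)) for n, p in config.class_proportions.items()}
    nucleus = _nucleus(size, targets.get("built_up", 0))
    t0 = np.zeros((size, size), dtype=np.int64)
    t0[nucleus] = LAND_USE_CODES["built_up"]
    rural_targets = {n: c for n, c in targets.items() if n != "built_up"}
    t0 = t0 + _rural_mosaic(rng, ~nucleus, rural_targets, config.smoothing_scale)

    t1 = _grow_compact(t0, config.densify_rate)
    t2 = _grow_dispersed(t1, config.disperse_rate, rng)
    t3 = _sprinkle(t2, config.sprinkle_rate, rng)

    return [
        LandUseGrid(values=v, cell_size=config.cell_size, year=y)
        for v, y in zip((t0, t1, t2, t3), config.years)
    ]


def stage_signature(series: list[LandUseGrid], edge_width: int = 1) -> "pd.DataFrame":
    """Directional per-stage indicators computed with the real pipeline.

    For each consecutive pair of dates: change in urban core share, change
    in urban islet patch count, and change in the mean rural core patch
    size (pooled over the non-urban classes).
    """
    import pandas as pd

    from .grid_io import class_mask
    from .metrics import core_share, patch_stats
    from .mspa import MspaParams, segment

    params = MspaParams(edge_width=edge_width)
    rows = []
    per_year = []
    for grid in series:
        urban_seg = segment(class_mask(grid, LAND_USE_CODES["built_up"]), params)
        share = core_share(urban_seg)
        stats = patch_stats(urban_seg, grid.cell_size, year=grid.year, land_use="built_up")
        islets = int(stats.loc[stats["morphology"] == "islet", "patch_count"].iloc[0])
        core_area = 0.0
        core_count = 0
        for code in RURAL_CODES:
            m = class_mask(grid, code)
            if not m.values.any():
                continue
            seg = segment(m, params)
            s = patch_stats(seg, grid.cell_size)
            row = s.loc[s["morphology"] == "core"].iloc[0]
            core_area += float(row["total_area_ha"])
            core_count += int(row["patch_count"])
        rural_core_mean = core_area / core_count if core_count else 0.0
        per_year.append((grid.year, share, islets, rural_core_mean))

    for (y0, s0, i0, m0), (y1, s1, i1, m1) in zip(per_year, per_year[1:]):
        rows.append(
            {
                "stage": f"{y0}-{y1}",
                "urban_core_share_change": s1 - s0,
                "urban_islet_count_change": i1 - i0,
                "rural_core_mean_size_change": m1 - m0,
            }
        )
    return pd.DataFrame(rows)
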