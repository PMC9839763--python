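"""End-to-end orchestration: rasters → MSPA → metrics → MFA → rapidity → report.

Two entry modes exist.  The full raster mode segments every land-use class
of every year, builds the structure-function tables, fits the multi-way
factor analysis and derives the rapidity statistics.  The coordinates mode
(`rapidity_from_coordinates`) skips the raster and factor stages entirely
and runs the pure-arithmetic rapidity analysis on a published coordinate
table — the path used with the shipped Rome coordinates.

Every run directory carries a ``run_metadata.json`` with the configuration
hash and package version so artifacts are traceable to their inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .grid_io import LandUseGrid, class_mask, read_grid, write_grid
from .metrics import build_sf_matrix, core_share, patch_stats, share_change_table, sf_change_table
from .mfa import align_axes, fit, standardize
from .mspa import MspaParams, segment
from .nomenclature import LAND_USE_CODES
from .rapidity import (
    RapidityResult,
    StageWindow,
    analyse,
    coordinates_from_mfa,
    load_axis_coordinates,
)
from .synthlandscape import SynthConfig, generate_series

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage-named pipeline failure."""


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Provide either ``grid_paths`` (mapping year → raster path) or a
    ``synth`` generator configuration.  Stage windows default to the
    consecutive year pairs plus the long-term first-to-last window.
    """

    grid_paths: dict[int, str] = field(default_factory=dict)
    synth: SynthConfig | None = None
    edge_width: int = 1
    mfa_variant: str = "mfa"
    out_dir: str = "morphoscape_run"
    alignment_reference: str | None = None
    include_long_term: bool = True

    def __post_init__(self) -> None:
        if not self.grid_paths and self.synth is None:
            raise ValueError("config needs grid_paths or a synth block")
        years = self.years()
        if len(years) < 2:
            raise ValueError("need at least 2 years")
        if sorted(years) != list(years) or len(set(years)) != len(years):
            raise ValueError("years must be strictly increasing")

    def years(self) -> list[int]:
        if self.grid_paths:
            return list(self.grid_paths)
        return list(self.synth.years)

    def windows(self) -> list[StageWindow]:
        years = self.years()
        wins = [StageWindow(f"{a}-{b}", a, b) for a, b in zip(years, years[1:])]
        if self.include_long_term and len(years) > 2:
            wins.append(StageWindow("long_term", years[0], years[-1]))
        return wins

    def config_hash(self) -> str:
        def _default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o).__name__)

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=_default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_series(config: PipelineConfig) -> list[LandUseGrid]:
    if config.grid_paths:
        return [read_grid(p, year=y) for y, p in config.grid_paths.items()]
    return generate_series(config.synth)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis and write all artifacts into the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()
    stage = "load"
    try:
        series = _load_series(config)
        params = MspaParams(edge_width=config.edge_width)

        stage = "mspa"
        t0 = time.perf_counter()
        stats_frames = []
        shares: dict[str, dict[int, float]] = {}
        for grid in series:
            for name, code in LAND_USE_CODES.items():
                mask = class_mask(grid, code)
                seg = segment(mask, params, class_code=code)
                counts = seg.pixel_counts()
                if sum(counts.values()) != int(mask.values.sum()):
                    raise PipelineError(
                        f"mspa: partition broken for {name} {grid.year}"
                    )
                seg_grid = LandUseGrid(
                    values=seg.types.astype(int), cell_size=grid.cell_size, year=grid.year
                )
                write_grid(seg_grid, out / f"segmentation_{grid.year}_{name}.asc")
                stats_frames.append(
                    patch_stats(seg, grid.cell_size, year=grid.year, land_use=name)
                )
                if mask.values.any():
                    shares.setdefault(name, {})[grid.year] = core_share(seg)
        logger.info("mspa stage done in %.1fs", time.perf_counter() - t0)

        stage = "metrics"
        stats = pd.concat(stats_frames, ignore_index=True)
        stats.to_csv(out / "patch_stats.csv", index=False)
        years = [g.year for g in series]
        matrices = {y: build_sf_matrix(stats, y) for y in years}
        for y, m in matrices.items():
            m.to_csv(out / f"sf_matrix_{y}.csv")
        stage_windows = [(w.label, w.t0, w.t1) for w in config.windows() if w.label != "long_term"]
        share_df = pd.DataFrame(shares).T.reindex(columns=years)
        share_df.to_csv(out / "core_share.csv")
        share_change_table(share_df, stage_windows).to_csv(
            out / "change_core_share.csv", index=False
        )
        sf_change_table(matrices, stage_windows).to_csv(
            out / "change_mean_patch_size.csv", index=False
        )

        stage = "mfa"
        t0 = time.perf_counter()
        standardized = {y: standardize(m) for y, m in matrices.items()}
        result = fit(standardized, variant=config.mfa_variant)
        logger.info(
            "mfa: %d retained axes, first axis %.1f%% (%.1fs)",
            result.n_retained,
            result.percent_variance[0],
            time.perf_counter() - t0,
        )
        if config.alignment_reference:
            result = align_axes(result, load_axis_coordinates(config.alignment_reference))
        eig = pd.DataFrame(
            {
                "eigenvalue": result.eigenvalues,
                "percent_variance": result.percent_variance,
            }
        )
        eig.index.name = "axis"
        eig.to_csv(out / "mfa_eigenvalues.csv")
        result.rv.to_csv(out / "mfa_rv.csv")
        for y in years:
            result.partial_loadings[y].to_csv(out / f"mfa_partial_loadings_{y}.csv")
            result.partial_scores[y].to_csv(out / f"mfa_partial_scores_{y}.csv")
        summary = {
            "variant": result.variant,
            "n_retained": result.n_retained,
            "eigenvalues": result.eigenvalues.tolist(),
            "percent_variance": result.percent_variance.tolist(),
            "weights": {str(k): v for k, v in result.weights.items()},
        }
        (out / "mfa_summary.json").write_text(json.dumps(summary, indent=2))

        stage = "rapidity"
        coords = coordinates_from_mfa(result)
        rap = analyse(coords, config.windows())
        rap.values.to_csv(out / "rapidity.csv", index=False)
        _write_fast_slow(rap, out / "fast_slow.txt")

        stage = "report"
        report = write_report(
            {
                "config_hash": config.config_hash(),
                "years": years,
                "matrices": matrices,
                "share_df": share_df,
                "mfa_summary": summary,
                "rapidity": rap,
            }
        )
        (out / "report.md").write_text(report)
        (out / "run_metadata.json").write_text(
            json.dumps(
                {
                    "config_hash": config.config_hash(),
                    "version": __version__,
                    "elapsed_s": round(time.perf_counter() - t_start, 2),
                },
                indent=2,
            )
        )
    except PipelineError:
        raise
    except Exception as exc:  # annotate with the failing stage
        raise PipelineError(f"{stage}: {exc}") from exc
    return out


def rapidity_from_coordinates(
    path: str | Path,
    windows: list[StageWindow] | None = None,
) -> RapidityResult:
    """Pure-arithmetic rapidity analysis from a coordinates CSV.

    No raster or factor-analysis code runs; this is the entry point for
    published coordinate tables.
    """
    coords = load_axis_coordinates(path)
    return analyse(coords, windows)


def _write_fast_slow(rap: RapidityResult, path: Path) -> None:
    lines = ["fast/slow classification (above/below the dimension median R')", ""]
    for (dim, win), grp in rap.labels.groupby(["dimension", "window"], sort=False):
        lines.append(f"[{dim} | {win}]")
        for row in grp.itertuples():
            lines.append(f"  {row.entity:<14s} {row.label}")
        lines.append("")
    path.write_text("\n".join(lines))


def write_report(artifacts: dict) -> str:
    """Render a human-readable markdown summary of a run."""
    lines = [
        "# morphoscape run report",
        "",
        f"config hash: `{artifacts.get('config_hash', 'n/a')}`",
        "",
    ]
    matrices = artifacts.get("matrices") or {}
    if not matrices:
        lines += ["## Mean patch size", "", "_no data_", ""]
    for y, m in matrices.items():
        lines += [f"## Mean patch size (ha), {y}", "", "```\n" + m.round(2).to_string() + "\n```", ""]
    share_df = artifacts.get("share_df")
    if share_df is not None and not share_df.empty:
        lines += ["## Core share (%) by class and year", "", "```\n" + share_df.round(1).to_string() + "\n```", ""]
    else:
        lines += ["## Core share (%)", "", "_no data_", ""]
    summary = artifacts.get("mfa_summary")
    if summary:
        pv = ", ".join(f"{v:.1f}%" for v in summary["percent_variance"][: summary["n_retained"]])
        lines += [
            "## Multi-way factor analysis",
            "",
            f"variant: {summary['variant']}; retained axes: {summary['n_retained']} ({pv})",
            "",
        ]
    else:
        lines += ["## Multi-way factor analysis", "", "_no data_", ""]
    rap = artifacts.get("rapidity")
    if rap is not None:
        lines += ["## Rapidity of change (mean R' per dimension and window)", ""]
        lines += ["```\n" + rap.averages.round(4).to_string(index=False) + "\n```", ""]
    else:
        lines += ["## Rapidity of change", "", "_no data_", ""]
    return "\n".join(lines)
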