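"""End-to-end orchestration: load inputs, run every stage, write outputs.

Stage order: cover composition → heterogeneity H' → connectivity ECI →
HANPP → Le/IDC and configuration labels → ecosystem services → regressions.
Each stage logs one structured line with its parameters; outputs are
deterministic for a fixed config and seed. If the expert-response file is
absent the pipeline completes through IDC and skips the service stage with
a logged warning.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import complexity, connectivity, hanpp, hexgrid, raster as rasterio_, services
from .errors import ValidationError
from .legend import Legend, read_legend
from .regression import LinearFitResult, RegressionResult, linear_fit, stepwise_mrm

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All file paths and numeric options of a pipeline run.

    Paths may be None when a stage is to be skipped (expert responses) or
    when inputs are generated in memory (synthetic runs).
    """

    raster_path: str | None = None
    legend_path: str | None = None
    affinity_path: str | None = None
    barriers_path: str | None = None
    npp_path: str | None = None
    expert_path: str | None = None
    out_dir: str = "out"

    cell_area_ha: float = 50.0
    min_valid_fraction: float = 0.5
    orientation: str = "flat_top"

    eci_exponent: str = "ratio_cubed"
    eci_connectivity: int = 8
    eci_base_cost: float = 1.0
    eci_barrier_affinity: float = 0.1
    eci_min_patch_cells: int = 1
    eci_x_t_override: float | None = None

    shannon_categories: int | None = None  # None: infer J from the legend
    le_a: float = 1.0
    le_b: float = 1.0
    mf_threshold: float = 3.0
    bands: complexity.ConfigurationBands = field(
        default_factory=complexity.ConfigurationBands
    )
    stepwise_criterion: str = "aic"
    seed: int = 0

    # raster georeferencing for formats that carry none (TIFF)
    raster_cell_size: float = 100.0
    raster_nodata: int = -9999

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        bands = data.pop("bands", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if bands:
            cfg.bands = complexity.ConfigurationBands(
                anthropic=tuple(bands.get("anthropic", (0.05, 0.3))),
                natural=tuple(bands.get("natural", (0.3, 0.5))),
                mosaic_min=float(bands.get("mosaic_min", 0.5)),
                natural_dominance=float(bands.get("natural_dominance", 0.5)),
            )
        return cfg


@dataclass
class InputBundle:
    raster: rasterio_.LandCoverRaster
    legend: Legend
    affinity: connectivity.AffinityMatrix
    barriers: connectivity.BarrierSpec
    npp: hanpp.NppTable
    responses: pd.DataFrame | None = None


def load_inputs(config: RunConfig) -> InputBundle:
    """Load and cross-validate every input file; failures are aggregated."""
    problems: list[str] = []
    for name in ("raster_path", "legend_path", "affinity_path", "barriers_path", "npp_path"):
        p = getattr(config, name)
        if p is None:
            problems.append(f"{name} is not set")
        elif not Path(p).exists():
            problems.append(f"{name}: file not found: {p}")
    if problems:
        raise ValidationError("missing pipeline inputs", problems)

    legend = read_legend(config.legend_path, nodata=config.raster_nodata)
    rp = Path(config.raster_path)
    if rp.suffix.lower() in (".tif", ".tiff"):
        rast = rasterio_.read_tiff(
            rp, cell_size=config.raster_cell_size, nodata=config.raster_nodata
        )
    else:
        rast = rasterio_.read_ascii_grid(rp, nodata=config.raster_nodata)
    affinity = connectivity.read_affinity(config.affinity_path)
    barriers = connectivity.read_barriers(config.barriers_path)
    npp = hanpp.read_npp(config.npp_path)

    try:
        rast.validate_against(legend)
    except ValidationError as e:
        problems.extend(e.details or [str(e)])
    present = set(np.unique(rast.grid[rast.valid_mask]).tolist())
    missing_npp = sorted(present - set(npp.classes))
    if missing_npp:
        problems.append(f"classes missing from NPP table: {missing_npp}")
    fa_set = set(legend.functional_areas)
    bad_fa = sorted(set(affinity.areas) - fa_set)
    if bad_fa:
        problems.append(
            f"affinity matrix areas {bad_fa} not in configured functional areas "
            f"{sorted(fa_set)}"
        )
    responses = None
    if config.expert_path is not None:
        if Path(config.expert_path).exists():
            try:
                responses = services.read_responses(config.expert_path)
            except ValidationError as e:
                problems.extend(e.details or [str(e)])
        else:
            logger.warning(
                "expert response file %s not found; service stage will be skipped",
                config.expert_path,
            )
    if problems:
        raise ValidationError("input validation failed", problems)
    return InputBundle(
        raster=rast, legend=legend, affinity=affinity, barriers=barriers,
        npp=npp, responses=responses,
    )


@dataclass
class PipelineResult:
    metrics: pd.DataFrame
    grid: hexgrid.HexGrid
    composition: hexgrid.CoverComposition
    eci: connectivity.EciField
    area_table: rasterio_.AreaTable
    regression: RegressionResult | None = None
    idc_esc_fit: LinearFitResult | None = None
    warnings: list[str] = field(default_factory=list)


def run_pipeline(bundle: InputBundle, config: RunConfig) -> PipelineResult:
    """Execute all stages on loaded inputs and return the per-hexagon table."""
    warnings_: list[str] = []
    rast, legend = bundle.raster, bundle.legend

    logger.info("stage=areas cell_area_ha=%s", config.cell_area_ha)
    area_table = rasterio_.summarize_areas(rast, legend)

    rows, cols = rast.shape
    x0, ytop = rast.origin
    extent = (x0, ytop - rows * rast.cell_size, x0 + cols * rast.cell_size, ytop)
    grid = hexgrid.build_hex_grid(extent, config.cell_area_ha, config.orientation)
    logger.info("stage=grid n_cells=%d equivalents=%d", grid.n_cells, grid.whole_cell_equivalents)

    comp = hexgrid.compute_composition(rast, grid, config.min_valid_fraction)
    logger.info(
        "stage=composition hexagons=%d included=%d min_valid_fraction=%s",
        len(comp.hex_ids), len(comp.included_ids), config.min_valid_fraction,
    )

    categories = legend.habitat_categories()
    if config.shannon_categories is not None and config.shannon_categories != len(categories):
        warnings_.append(
            f"configured J={config.shannon_categories} differs from legend categories "
            f"({len(categories)}); legend categories used"
        )
    hprime = complexity.shannon(comp, legend)
    logger.info("stage=shannon J=%d", len(categories))

    eci_field = connectivity.compute_eci(
        rast, legend, bundle.affinity, bundle.barriers,
        composition=comp,
        connectivity=config.eci_connectivity,
        base_cost=config.eci_base_cost,
        barrier_affinity=config.eci_barrier_affinity,
        min_patch_cells=config.eci_min_patch_cells,
        x_t_override=config.eci_x_t_override,
        exponent=config.eci_exponent,
    )
    logger.info(
        "stage=eci areas=%d exponent=%s connectivity=%d",
        len(eci_field.per_area), config.eci_exponent, config.eci_connectivity,
    )

    hanpp_class = hanpp.compute_hanpp_class(bundle.npp)
    hex_hanpp = hanpp.hanpp_hex(comp, hanpp_class)
    logger.info("stage=hanpp classes=%d", len(hanpp_class))

    included = comp.included_ids
    metrics = pd.DataFrame(index=pd.Index(included, name="hex_id"))
    metrics["hprime"] = hprime.loc[included]
    metrics["eci"] = eci_field.hexagon_mean.loc[included].clip(0.0, 10.0)
    metrics["hanpp_tC_ha"] = hex_hanpp["hanpp_tC_ha"]
    metrics["hanpp_pct"] = hex_hanpp["hanpp_pct"]
    metrics["le"] = complexity.landscape_complexity(
        metrics["hprime"], metrics["eci"], config.le_a, config.le_b
    )
    metrics["idc"] = complexity.idc(metrics["le"], metrics["hanpp_pct"])
    natural = comp.natural_fraction(legend).loc[included]
    metrics["config_label"] = complexity.classify_configuration(
        metrics["idc"], natural, config.bands
    )
    logger.info("stage=idc a=%s b=%s", config.le_a, config.le_b)

    if bundle.responses is not None:
        matrix = services.aggregate_panel(bundle.responses)
        esc_i = services.cover_capacity(matrix)
        mf_i = services.cover_multifunctionality(matrix, threshold=config.mf_threshold)
        hex_scores = services.esc_hex(comp, esc_i, mf_i)
        metrics["esc"] = hex_scores["esc"]
        metrics["mf"] = hex_scores["mf"]
        logger.info("stage=services threshold=%s", config.mf_threshold)
    else:
        warnings_.append("no expert responses: ESC/MF skipped")
        logger.warning("stage=services skipped (no expert responses)")

    regression = None
    fit = None
    predictors = comp.proportions.loc[included]
    predictors.columns = [
        legend[int(c)].name if int(c) in legend else str(c) for c in predictors.columns
    ]
    if len(included) >= predictors.shape[1] + 2:
        regression = stepwise_mrm(
            metrics["idc"], predictors, criterion=config.stepwise_criterion
        )
        logger.info("stage=regression criterion=%s n=%d", config.stepwise_criterion, len(included))
    else:
        warnings_.append(
            f"too few hexagons ({len(included)}) for stepwise regression on "
            f"{predictors.shape[1]} covers"
        )
    if "esc" in metrics.columns and metrics["idc"].nunique() > 1:
        fit = linear_fit(metrics["idc"].to_numpy(), metrics["esc"].to_numpy())
        logger.info("stage=idc_esc_fit n=%d", fit.n)

    return PipelineResult(
        metrics=metrics,
        grid=grid,
        composition=comp,
        eci=eci_field,
        area_table=area_table,
        regression=regression,
        idc_esc_fit=fit,
        warnings=warnings_,
    )


def write_outputs(result: PipelineResult, out_dir: str | Path) -> list[Path]:
    """Write the standard output set; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    metrics_path = out / "hex_metrics.csv"
    result.metrics.to_csv(metrics_path, float_format="%.6f")
    written.append(metrics_path)

    areas_path = out / "area_table.csv"
    result.area_table.to_csv(areas_path)
    written.append(areas_path)

    doc = result.grid.to_geojson()
    for feat in doc["features"]:
        hid = feat["properties"]["hex_id"]
        if hid in result.metrics.index:
            for col in result.metrics.columns:
                v = result.metrics.loc[hid, col]
                feat["properties"][col] = v if isinstance(v, str) else float(v)
    geojson_path = out / "hexagons.geojson"
    geojson_path.write_text(json.dumps(doc))
    written.append(geojson_path)

    if result.regression is not None:
        rep = out / "regression.txt"
        rep.write_text(result.regression.report() + "\n")
        result.regression.to_json(out / "regression.json")
        written += [rep, out / "regression.json"]
    if result.idc_esc_fit is not None:
        fit_path = out / "idc_esc_fit.json"
        fit_path.write_text(json.dumps(dataclasses.asdict(result.idc_esc_fit), indent=2))
        written.append(fit_path)
    return written
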