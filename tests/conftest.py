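"""Shared fixtures: small legends/rasters and one session-scoped synthetic run."""

import numpy as np
import pytest

from landmetab import pipeline, synthetic
from landmetab.legend import Legend, LegendEntry
from landmetab.raster import LandCoverRaster


@pytest.fixture
def small_legend() -> Legend:
    """Five-class legend: forest, mosaic, pasture, water, urban (barrier)."""
    entries = {
        1: LegendEntry(1, "Forest", "forest_seminatural", "Forest", "forest", "forest"),
        2: LegendEntry(2, "Mosaic", "agricultural", "Mosaic", "heterogeneous_crops",
                       "agroforestry_mosaic"),
        3: LegendEntry(3, "Pasture", "agricultural", "Pasture", "pastures", "pastures"),
        4: LegendEntry(4, "River", "water", "Water", "water", "water"),
        5: LegendEntry(5, "Urban", "built", "Urban", "no_habitat", None, True),
    }
    return Legend(entries=entries)


def make_raster(grid, cell_size=100.0, nodata=-9999) -> LandCoverRaster:
    grid = np.asarray(grid, dtype=np.int64)
    return LandCoverRaster(
        grid=grid,
        cell_size=cell_size,
        origin=(0.0, grid.shape[0] * cell_size),
        nodata=nodata,
    )


@pytest.fixture
def uniform_raster() -> LandCoverRaster:
    return make_raster(np.full((12, 12), 1))


@pytest.fixture(scope="session")
def ucrv_run():
    """One full synthetic run of the default valley/slope/highland scenario."""
    scenario = synthetic.ucrv_like_scenario(seed=1)
    rast, legend = synthetic.generate_landscape(scenario)
    npp = synthetic.generate_npp(legend, seed=1)
    panel = synthetic.generate_expert_panel(synthetic.PanelScenario(seed=1), legend=legend)
    bundle = pipeline.InputBundle(
        raster=rast,
        legend=legend,
        affinity=synthetic.default_affinity(),
        barriers=synthetic.default_barriers(),
        npp=npp,
        responses=panel,
    )
    config = pipeline.RunConfig(cell_area_ha=50.0)
    result = pipeline.run_pipeline(bundle, config)
    return {
        "scenario": scenario,
        "raster": rast,
        "legend": legend,
        "bundle": bundle,
        "config": config,
        "result": result,
    }


def hexagon_band(run, hex_id) -> str:
    """Band name of a hexagon by its center column in the scenario rasters."""
    grid = run["result"].grid
    center_x = {c.hex_id: c.center[0] for c in grid.cells}[hex_id]
    col = center_x / run["raster"].cell_size
    for name, lo, hi in run["scenario"].band_columns():
        if lo <= col < hi:
            return name
    return "edge"
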