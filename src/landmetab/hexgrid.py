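"""Equal-area hexagonal analysis grids and per-hexagon cover composition.

The study design divides a planar extent into equal-area hexagons (the
analysis units) and expresses every landscape metric as a statistic over the
raster cells whose centers fall inside each hexagon. Interior hexagons are
exactly equal in area; hexagons straddling the extent edge are clipped and
either renormalised or excluded depending on how much valid data they hold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, box

from .errors import EmptyResultError, InvalidArgumentError
from .legend import Legend
from .raster import M2_PER_HA, LandCoverRaster

Extent = tuple[float, float, float, float]  # xmin, ymin, xmax, ymax


@dataclass(frozen=True)
class HexCell:
    hex_id: int
    center: tuple[float, float]
    polygon: Polygon
    area_ha: float
    clipped: bool


@dataclass
class HexGrid:
    cells: list[HexCell]
    cell_area_ha: float
    orientation: str
    extent: Extent

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def whole_cell_equivalents(self) -> int:
        """Number of whole analysis units needed to tile the extent:
        ceil(extent area / unit area)."""
        xmin, ymin, xmax, ymax = self.extent
        extent_ha = (xmax - xmin) * (ymax - ymin) / M2_PER_HA
        return math.ceil(extent_ha / self.cell_area_ha - 1e-9)

    @property
    def total_area_ha(self) -> float:
        return sum(c.area_ha for c in self.cells)

    def polygons(self) -> list[Polygon]:
        return [c.polygon for c in self.cells]

    def to_geojson(self, path: str | Path | None = None) -> dict:
        features = []
        for c in self.cells:
            features.append(
                {
                    "type": "Feature",
                    "properties": {"hex_id": c.hex_id, "area_ha": c.area_ha},
                    "geometry": shapely.geometry.mapping(c.polygon),
                }
            )
        doc = {"type": "FeatureCollection", "features": features}
        if path is not None:
            Path(path).write_text(json.dumps(doc))
        return doc


def _hexagon(cx: float, cy: float, s: float, orientation: str) -> Polygon:
    if orientation == "flat_top":
        angles = np.deg2rad(np.arange(0, 360, 60))
    else:  # pointy_top
        angles = np.deg2rad(np.arange(30, 390, 60))
    return Polygon(zip(cx + s * np.cos(angles), cy + s * np.sin(angles)))


def build_hex_grid(
    extent: Extent, cell_area_ha: float, orientation: str = "flat_top"
) -> HexGrid:
    """Tile ``extent`` (map metres) with regular hexagons of ``cell_area_ha``.

    Hexagons are generated row-wise from the top-left of the extent; cells
    overhanging the edge are clipped to the extent rectangle, so interior
    cells all share the exact nominal area while boundary cells are smaller.
    """
    if orientation not in ("flat_top", "pointy_top"):
        raise InvalidArgumentError(f"unknown orientation {orientation!r}")
    if cell_area_ha <= 0:
        raise InvalidArgumentError("cell_area must be > 0")
    xmin, ymin, xmax, ymax = extent
    if xmax <= xmin or ymax <= ymin:
        raise InvalidArgumentError("extent must have positive width and height")

    area_m2 = cell_area_ha * M2_PER_HA
    s = math.sqrt(2.0 * area_m2 / (3.0 * math.sqrt(3.0)))  # side length
    dy = math.sqrt(3.0) * s  # center spacing across rows (flat-top)
    dx = 1.5 * s  # center spacing across columns (flat-top)

    clip_box = box(xmin, ymin, xmax, ymax)
    raw: list[tuple[float, float, Polygon]] = []

    if orientation == "flat_top":
        ncols = int(math.ceil((xmax - xmin) / dx)) + 2
        nrows = int(math.ceil((ymax - ymin) / dy)) + 2
        for c in range(-1, ncols):  # column -1 fills the left-edge notches
            cx = xmin + s + c * dx
            if cx + s < xmin:
                continue
            # odd columns shift up half a row so the tiling covers the top edge
            y_top = ymax - dy / 2.0 + (dy / 2.0 if c % 2 else 0.0)
            for r in range(nrows):
                cy = y_top - r * dy
                if cx - s > xmax or cy + dy / 2.0 < ymin:
                    continue
                raw.append((cx, cy, _hexagon(cx, cy, s, orientation)))
    else:
        # pointy-top: transpose the roles of x and y
        for r in range(-1, int(math.ceil((ymax - ymin) / dx)) + 2):
            cy = ymax - s - r * dx
            if cy - s > ymax:
                continue
            # odd rows shift left half a column so the left edge stays covered
            x_left = xmin + dy / 2.0 - (dy / 2.0 if r % 2 else 0.0)
            for c in range(int(math.ceil((xmax - xmin) / dy)) + 3):
                cx = x_left + c * dy
                if cy + s < ymin or cx - dy / 2.0 > xmax:
                    continue
                raw.append((cx, cy, _hexagon(cx, cy, s, orientation)))

    kept: list[tuple[float, float, Polygon, float, bool]] = []
    for cx, cy, poly in raw:
        inter = poly.intersection(clip_box)
        if inter.is_empty or inter.area < 1e-9 * area_m2:
            continue
        clipped = inter.area < poly.area * (1.0 - 1e-9)
        kept.append((cx, cy, inter if clipped else poly, inter.area, clipped))

    if not kept:
        raise EmptyResultError("extent too small to hold any hexagon fragment")

    # row-major ids from the top-left: sort by descending y, then ascending x
    kept.sort(key=lambda t: (-round(t[1], 6), round(t[0], 6)))
    cells = [
        HexCell(
            hex_id=i,
            center=(cx, cy),
            polygon=poly,
            area_ha=area / M2_PER_HA,
            clipped=clipped,
        )
        for i, (cx, cy, poly, area, clipped) in enumerate(kept)
    ]
    return HexGrid(
        cells=cells, cell_area_ha=cell_area_ha, orientation=orientation, extent=extent
    )


@dataclass
class CoverComposition:
    """Per-hexagon cover proportions P_ij.

    ``proportions`` is indexed by hex_id with one column per class code; rows
    of included hexagons sum to 1 over valid cells. ``cell_to_hex`` maps each
    raster cell to its hexagon (−1 where unassigned), enabling zonal means of
    arbitrary cell fields on the identical assignment.
    """

    proportions: pd.DataFrame
    valid_fraction: pd.Series
    included: pd.Series
    cell_to_hex: np.ndarray
    valid_cells: pd.Series

    @property
    def hex_ids(self) -> list[int]:
        return list(self.proportions.index)

    @property
    def included_ids(self) -> list[int]:
        return list(self.included.index[self.included])

    def natural_fraction(self, legend: Legend) -> pd.Series:
        """Share of each hexagon under natural cover (forest/seminatural + water)."""
        nat = [c for c in legend.natural_codes() if c in self.proportions.columns]
        return self.proportions[nat].sum(axis=1) if nat else pd.Series(
            0.0, index=self.proportions.index
        )

    def zonal_mean(self, field: np.ndarray, valid: np.ndarray | None = None) -> pd.Series:
        """Mean of a per-cell field over each hexagon's (valid) cells."""
        if field.shape != self.cell_to_hex.shape:
            raise InvalidArgumentError("field shape does not match the composition raster")
        hexes = self.cell_to_hex.ravel()
        vals = np.asarray(field, dtype=float).ravel()
        ok = hexes >= 0
        if valid is not None:
            ok &= valid.ravel()
        ok &= np.isfinite(vals)
        sums = np.bincount(hexes[ok], weights=vals[ok], minlength=len(self.proportions))
        counts = np.bincount(hexes[ok], minlength=len(self.proportions))
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        return pd.Series(means[: len(self.proportions)], index=self.proportions.index)


def compute_composition(
    raster: LandCoverRaster,
    grid: HexGrid,
    min_valid_fraction: float = 0.5,
) -> CoverComposition:
    """Tally raster cell centers per hexagon into cover proportions.

    A cell belongs to the hexagon containing its center; centers on shared
    edges go to the lower hex_id. Hexagons whose valid-data area falls below
    ``min_valid_fraction`` of their polygon area are flagged excluded (their
    proportions are still reported, renormalised over valid cells).
    """
    if not 0.0 <= min_valid_fraction <= 1.0:
        raise InvalidArgumentError("min_valid_fraction must be within [0, 1]")
    xs, ys = raster.cell_centers()
    points = shapely.points(xs, ys)
    tree = shapely.STRtree(grid.polygons())
    p_idx, h_idx = tree.query(points, predicate="intersects")
    if len(p_idx) == 0:
        raise EmptyResultError("raster and hexagon grid do not overlap")

    # ties on edges: containing hexagon with the lowest hex_id wins
    order = np.lexsort((h_idx, p_idx))
    p_sorted, h_sorted = p_idx[order], h_idx[order]
    first = np.ones(len(p_sorted), dtype=bool)
    first[1:] = p_sorted[1:] != p_sorted[:-1]
    assign = np.full(xs.shape[0], -1, dtype=np.int64)
    assign[p_sorted[first]] = h_sorted[first]

    cell_to_hex = assign.reshape(raster.shape)
    valid = raster.valid_mask
    hex_ids = np.arange(grid.n_cells)

    flat_hex = cell_to_hex.ravel()
    flat_code = raster.grid.ravel()
    ok = (flat_hex >= 0) & valid.ravel()
    codes = np.unique(flat_code[ok])
    counts = pd.DataFrame(0.0, index=hex_ids, columns=[int(c) for c in codes])
    for c in codes:
        sel = ok & (flat_code == c)
        counts[int(c)] = np.bincount(flat_hex[sel], minlength=grid.n_cells)

    valid_counts = counts.sum(axis=1)
    poly_area_ha = pd.Series([cell.area_ha for cell in grid.cells], index=hex_ids)
    valid_fraction = (valid_counts * raster.cell_area_ha / poly_area_ha).clip(upper=1.0)
    # a hexagon without a single valid cell carries no composition at all
    included = (valid_fraction >= min_valid_fraction) & (valid_counts > 0)

    props = counts.div(valid_counts.replace(0, np.nan), axis=0).fillna(0.0)
    props.index.name = "hex_id"
    return CoverComposition(
        proportions=props,
        valid_fraction=valid_fraction,
        included=included,
        cell_to_hex=cell_to_hex,
        valid_cells=valid_counts,
    )
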