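"""Categorical land-cover rasters: IO, validation, reclassification, area accounting.

The raster model is deliberately minimal: a row-major integer grid with a
top-left origin in planar (projected, equal-area) map coordinates and a
square cell size in metres. Areas are cell counts times the cell area; no
spherical correction is applied and no reprojection is performed.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyResultError, InvalidArgumentError, ValidationError
from .legend import Legend

M2_PER_HA = 10_000.0


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (report formatting; numpy rounds half-to-even)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass
class LandCoverRaster:
    """Integer-coded categorical grid.

    ``origin`` is the map coordinate of the *top-left corner* of cell (0, 0);
    y decreases with increasing row index.
    """

    grid: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: int = -9999

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2 or self.grid.shape[0] < 1 or self.grid.shape[1] < 1:
            raise InvalidArgumentError("raster grid must be 2-D with at least one cell")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise InvalidArgumentError("raster grid must hold integer class codes")
        if self.cell_size <= 0:
            raise InvalidArgumentError("cell_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size**2 / M2_PER_HA

    @property
    def valid_mask(self) -> np.ndarray:
        return self.grid != self.nodata

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) map coordinates of every cell center, row-major flattened."""
        rows, cols = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(cols) + 0.5) * self.cell_size
        ys = y0 - (np.arange(rows) + 0.5) * self.cell_size
        xx, yy = np.meshgrid(xs, ys)
        return xx.ravel(), yy.ravel()

    def validate_against(self, legend: Legend) -> None:
        """Every non-nodata code must exist in the legend."""
        codes = np.unique(self.grid[self.valid_mask])
        unknown = [int(c) for c in codes if int(c) not in legend]
        if unknown:
            raise ValidationError(
                "raster codes missing from legend",
                [f"code {c} present in raster but not in legend" for c in unknown],
            )


# ---------------------------------------------------------------------------
# File formats


def read_ascii_grid(path: str | Path, nodata: int | None = None) -> LandCoverRaster:
    """Read an ESRI ASCII grid (.asc). Header nodata is honoured unless overridden."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        nheader = 0
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
                nheader += 1
            else:
                fh.seek(pos)
                break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValidationError(f"ASCII grid {path}: missing header field {key}")
    grid = np.loadtxt(path, skiprows=nheader, dtype=np.int64)
    grid = np.atleast_2d(grid)
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValidationError(
            f"ASCII grid {path}: data shape {grid.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    cell = header["cellsize"]
    x0 = header.get("xllcorner", 0.0)
    ytop = header.get("yllcorner", 0.0) + int(header["nrows"]) * cell
    nd = nodata if nodata is not None else int(header.get("nodata_value", -9999))
    return LandCoverRaster(grid=grid, cell_size=cell, origin=(x0, ytop), nodata=nd)


def write_ascii_grid(raster: LandCoverRaster, path: str | Path) -> None:
    path = Path(path)
    rows, cols = raster.shape
    x0, ytop = raster.origin
    yll = ytop - rows * raster.cell_size
    with path.open("w") as fh:
        fh.write(
            f"ncols {cols}\nnrows {rows}\n"
            f"xllcorner {x0:.6f}\nyllcorner {yll:.6f}\n"
            f"cellsize {raster.cell_size:.6f}\nNODATA_value {raster.nodata}\n"
        )
        np.savetxt(fh, raster.grid, fmt="%d")


def read_tiff(
    path: str | Path,
    cell_size: float,
    origin: tuple[float, float] = (0.0, 0.0),
    nodata: int = -9999,
) -> LandCoverRaster:
    """Read a single-band integer TIFF. Cell size/origin are supplied by the
    caller (the pipeline's config), since plain TIFF carries no georeferencing."""
    import tifffile

    grid = np.asarray(tifffile.imread(str(path)))
    if grid.ndim != 2:
        raise ValidationError(f"TIFF {path}: expected a single band, got shape {grid.shape}")
    return LandCoverRaster(
        grid=grid.astype(np.int64), cell_size=cell_size, origin=origin, nodata=nodata
    )


def write_tiff(raster: LandCoverRaster, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(str(path), raster.grid.astype(np.int32))


# ---------------------------------------------------------------------------
# Reclassification


def reclassify(raster: LandCoverRaster, mapping: dict[int, int]) -> LandCoverRaster:
    """Map every class code through ``mapping``; nodata is preserved.

    Raises :class:`ValidationError` listing all codes present in the raster
    but absent from the mapping.
    """
    present = np.unique(raster.grid[raster.valid_mask])
    unmapped = [int(c) for c in present if int(c) not in mapping]
    if unmapped:
        raise ValidationError(
            "reclassification mapping incomplete",
            [f"code {c} has no target group" for c in unmapped],
        )
    out = raster.grid.copy()
    for src in present:
        out[raster.grid == src] = mapping[int(src)]
    out[~raster.valid_mask] = raster.nodata
    return LandCoverRaster(
        grid=out, cell_size=raster.cell_size, origin=raster.origin, nodata=raster.nodata
    )


# ---------------------------------------------------------------------------
# Area accounting


@dataclass
class AreaTable:
    """Per-class and per-group surface accounting.

    ``per_class`` columns: typology, land_cover, reclass, area_ha, percent.
    ``per_group`` columns: reclass, area_ha, percent (exact sums of members).
    Percentages are stored at full precision; use :meth:`formatted` for the
    one-decimal round-half-up report layout.
    """

    per_class: pd.DataFrame
    per_group: pd.DataFrame
    total_ha: float

    def group_area(self, group: str) -> float:
        sel = self.per_group.loc[self.per_group["reclass"] == group, "area_ha"]
        if sel.empty:
            raise KeyError(group)
        return float(sel.iloc[0])

    def class_percent(self, land_cover: str) -> float:
        sel = self.per_class.loc[self.per_class["land_cover"] == land_cover, "percent"]
        if sel.empty:
            raise KeyError(land_cover)
        return float(sel.iloc[0])

    def formatted(self) -> pd.DataFrame:
        out = self.per_class.copy()
        out["percent"] = out["percent"].map(lambda p: round_half_up(p, 1))
        return out

    def to_csv(self, path: str | Path) -> None:
        self.per_class.to_csv(path, index=False)


def area_table_from_areas(
    per_class: pd.DataFrame,
    group_col: str = "reclass",
    total_ha: float | None = None,
) -> AreaTable:
    """Build an :class:`AreaTable` from tabulated class areas.

    ``per_class`` needs columns ``typology, land_cover, reclass, area_ha``
    (plus ``group_col`` if it is not ``reclass``); percent is
    100 × area / grand total and group rows are exact member sums. The grand
    total defaults to the class sum; ``total_ha`` overrides it for source
    tables whose published denominator is the full study area rather than
    the tabulated classes.
    """
    df = per_class.copy()
    if (df["area_ha"] < 0).any():
        raise ValidationError("negative class area in area table")
    total = float(df["area_ha"].sum()) if total_ha is None else float(total_ha)
    if total <= 0:
        raise EmptyResultError("area table has zero total area")
    df["percent"] = 100.0 * df["area_ha"] / total
    groups = (
        df.groupby(group_col, sort=False)
        .agg(area_ha=("area_ha", "sum"), percent=("percent", "sum"))
        .reset_index()
        .rename(columns={group_col: "reclass"})
    )
    return AreaTable(per_class=df, per_group=groups, total_ha=total)


def ucrv_reference_areas() -> pd.DataFrame:
    """The published class-area table of the Upper Cauca River Valley.

    Columns: typology, land_cover, reclass, group, area_ha. The tabulated
    classes cover 99.4% of the 1,004,000 ha study area; percentages in the
    source use the full study area as denominator.
    """
    from importlib import resources

    with resources.files("landmetab.data").joinpath("ucrv_table1.csv").open() as fh:
        return pd.read_csv(fh)


def ucrv_reference_table() -> AreaTable:
    """Area accounting of the reference region (study-area denominator)."""
    return area_table_from_areas(
        ucrv_reference_areas(), group_col="group", total_ha=1_004_000.0
    )


def summarize_areas(raster: LandCoverRaster, legend: Legend) -> AreaTable:
    """Tabulate class areas (cell count × cell area) and group roll-ups."""
    raster.validate_against(legend)
    valid = raster.grid[raster.valid_mask]
    if valid.size == 0:
        raise EmptyResultError("raster contains only nodata cells")
    codes, counts = np.unique(valid, return_counts=True)
    rows = []
    for code, n in zip(codes, counts):
        e = legend[int(code)]
        rows.append(
            {
                "typology": e.typology,
                "land_cover": e.name,
                "reclass": e.reclass_group,
                "area_ha": float(n) * raster.cell_area_ha,
            }
        )
    return area_table_from_areas(pd.DataFrame(rows))
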