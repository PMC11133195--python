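"""Ecological connectivity via accumulated-cost (friction) surfaces.

The index rates every cell by how costly it is to reach the nearest source
patch of each functional ecological area b, where the traversal cost of a
cell is the inverse of the ecological affinity between its own functional
area and b, plus additive penalties around anthropogenic barriers (urban
fabric, infrastructure). The per-area score

    ECI_b = 10 − 9 · [ln(1 + X_i) / ln(1 + X_t)]³

maps accumulated cost X_i ∈ [0, X_t] onto [10, 1] (10 on source cells), and
the total index is the arithmetic mean of ECI_b over the m areas considered.
The cube steepens the decay so that moderate costs still score well — a
sigmoid-like profile. An alternative reading of the exponent (cube on the
denominator, i.e. 3·ln(1+X_t)) is available for sensitivity checks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra

from .errors import (
    EmptyResultError,
    InvalidArgumentError,
    ValidationError,
)
from .hexgrid import CoverComposition
from .legend import Legend
from .raster import LandCoverRaster


@dataclass
class AffinityMatrix:
    """Square affinity table over the functional ecological areas.

    Entries lie in (0, 1]: 1 on the diagonal (an area is fully permeable to
    itself), smaller values for ecologically distant pairs. Symmetric unless
    explicitly allowed otherwise.
    """

    table: pd.DataFrame
    allow_asymmetric: bool = False

    def __post_init__(self) -> None:
        t = self.table
        problems: list[str] = []
        if list(t.index) != list(t.columns):
            problems.append("row and column headers differ")
        vals = t.to_numpy(dtype=float)
        if not np.all((vals > 0) & (vals <= 1)):
            problems.append("entries must lie in (0, 1]")
        if t.shape[0] == t.shape[1]:
            if not np.allclose(np.diag(vals), 1.0):
                problems.append("diagonal entries must equal 1")
            if not self.allow_asymmetric and not np.allclose(vals, vals.T):
                problems.append("matrix not symmetric (set allow_asymmetric to override)")
        else:
            problems.append(f"matrix is {t.shape[0]}x{t.shape[1]}, expected square")
        if problems:
            raise ValidationError(
                f"invalid affinity matrix over areas {list(t.columns)}", problems
            )

    @property
    def areas(self) -> list[str]:
        return list(self.table.columns)

    def affinity(self, area: str, target: str) -> float:
        return float(self.table.loc[area, target])


def read_affinity(path: str | Path, allow_asymmetric: bool = False) -> AffinityMatrix:
    """CSV with functional-area names as both row index and column headers."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    return AffinityMatrix(table=df, allow_asymmetric=allow_asymmetric)


@dataclass(frozen=True)
class BarrierClass:
    code: int
    impact: float  # additive friction inside the halo
    halo_m: float
    impermeable: bool = False


@dataclass
class BarrierSpec:
    classes: dict[int, BarrierClass] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [
            f"class {c}: impact {b.impact} < 0 or halo {b.halo_m} < 0"
            for c, b in self.classes.items()
            if b.impact < 0 or b.halo_m < 0
        ]
        if bad:
            raise ValidationError("invalid barrier specification", bad)

    def get(self, code: int) -> BarrierClass | None:
        return self.classes.get(code)


def read_barriers(path: str | Path) -> BarrierSpec:
    """CSV with columns ``class,impact,halo_m,impermeable``."""
    df = pd.read_csv(path)
    classes = {
        int(r["class"]): BarrierClass(
            code=int(r["class"]),
            impact=float(r["impact"]),
            halo_m=float(r["halo_m"]),
            impermeable=str(r["impermeable"]).strip().lower() in ("1", "true", "yes"),
        )
        for _, r in df.iterrows()
    }
    return BarrierSpec(classes=classes)


@dataclass
class FrictionSurface:
    """Per-cell traversal cost toward one target functional area.

    ``cost`` is in cost units per cell length; ``mask`` marks impermeable
    (or nodata) cells excluded from traversal.
    """

    cost: np.ndarray
    mask: np.ndarray
    target_area: str
    cell_size: float

    def __post_init__(self) -> None:
        open_cost = self.cost[~self.mask]
        if open_cost.size and not np.all(np.isfinite(open_cost) & (open_cost > 0)):
            raise ValidationError("unmasked friction values must be positive and finite")


def build_friction(
    raster: LandCoverRaster,
    legend: Legend,
    affinity: AffinityMatrix,
    barriers: BarrierSpec,
    target_area: str,
    base_cost: float = 1.0,
    barrier_affinity: float = 0.1,
) -> FrictionSurface:
    """Friction = base_cost / affinity(area(cell), target) + barrier halo impacts.

    Permeable barrier cells cost ``base_cost / barrier_affinity``; impermeable
    ones are masked out. Each barrier class adds its ``impact`` to every cell
    within ``halo_m`` (Euclidean) of one of its cells.
    """
    if target_area not in affinity.areas:
        raise InvalidArgumentError(
            f"target area {target_area!r} not in affinity matrix areas {affinity.areas}"
        )
    if base_cost <= 0 or not 0 < barrier_affinity <= 1:
        raise InvalidArgumentError("base_cost must be > 0 and barrier_affinity in (0, 1]")

    raster.validate_against(legend)
    grid = raster.grid
    cost = np.full(grid.shape, np.nan)
    mask = ~raster.valid_mask

    unresolved: list[str] = []
    for code in np.unique(grid[raster.valid_mask]):
        e = legend[int(code)]
        sel = grid == code
        if e.functional_area is not None:
            aff = affinity.affinity(e.functional_area, target_area)
            cost[sel] = base_cost / aff
        elif e.barrier_flag:
            b = barriers.get(int(code))
            if b is not None and b.impermeable:
                mask[sel] = True
                cost[sel] = np.inf
            else:
                cost[sel] = base_cost / barrier_affinity
        else:
            unresolved.append(f"class {code} ({e.name}) has neither functional_area nor barrier_flag")
    if unresolved:
        raise ValidationError("classes unusable for the friction surface", unresolved)

    # additive halo impacts around each barrier class
    for code, b in barriers.classes.items():
        if b.impact <= 0:
            continue
        cells = grid == code
        if not cells.any():
            continue
        dist = ndimage.distance_transform_edt(~cells, sampling=raster.cell_size)
        halo = dist <= b.halo_m
        cost[halo & ~mask] += b.impact

    return FrictionSurface(
        cost=cost, mask=mask, target_area=target_area, cell_size=raster.cell_size
    )


@dataclass
class AccumulatedCost:
    """Least accumulated cost X_i from the nearest source cell (cost units,
    step lengths measured in cell widths). Unreachable open cells are +inf
    until clamped against the theoretical maximum."""

    cost: np.ndarray
    sources: np.ndarray


def _neighbor_offsets(connectivity: int) -> list[tuple[int, int, float]]:
    if connectivity == 4:
        return [(-1, 0, 1.0), (1, 0, 1.0), (0, -1, 1.0), (0, 1, 1.0)]
    if connectivity == 8:
        d = math.sqrt(2.0)
        return [
            (-1, 0, 1.0), (1, 0, 1.0), (0, -1, 1.0), (0, 1, 1.0),
            (-1, -1, d), (-1, 1, d), (1, -1, d), (1, 1, d),
        ]
    raise InvalidArgumentError("connectivity must be 4 or 8")


def accumulate_cost(
    friction: FrictionSurface,
    sources: np.ndarray | set[tuple[int, int]],
    connectivity: int = 8,
) -> AccumulatedCost:
    """Multi-source least-cost distance over the cell graph.

    Edge weight between neighbouring open cells a, b is
    mean(friction_a, friction_b) × step length (1 for rook moves, √2 for
    diagonal moves). Exact Dijkstra; deterministic.
    """
    offsets = _neighbor_offsets(connectivity)
    rows, cols = friction.cost.shape

    if isinstance(sources, set):
        src_mask = np.zeros((rows, cols), dtype=bool)
        for r, c in sources:
            src_mask[r, c] = True
    else:
        src_mask = np.asarray(sources, dtype=bool)
        if src_mask.shape != friction.cost.shape:
            raise InvalidArgumentError("source mask shape does not match friction grid")
    if not src_mask.any():
        raise InvalidArgumentError("at least one source cell is required")
    open_src = src_mask & ~friction.mask
    if not open_src.any():
        raise EmptyResultError("all source cells are masked (impermeable)")

    open_mask = ~friction.mask
    idx = -np.ones((rows, cols), dtype=np.int64)
    idx[open_mask] = np.arange(open_mask.sum())
    n = int(open_mask.sum())
    f = friction.cost

    rows_i, cols_i, data = [], [], []
    for dr, dc, step in offsets:
        # slice pairs (r, c) -> (r+dr, c+dc), keep both open
        r0, r1 = max(0, -dr), rows - max(0, dr)
        c0, c1 = max(0, -dc), cols - max(0, dc)
        a = np.s_[r0:r1, c0:c1]
        b = np.s_[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        both = open_mask[a] & open_mask[b]
        if not both.any():
            continue
        w = 0.5 * (f[a][both] + f[b][both]) * step
        rows_i.append(idx[a][both])
        cols_i.append(idx[b][both])
        data.append(w)
    if rows_i:
        graph = sparse.csr_matrix(
            (np.concatenate(data), (np.concatenate(rows_i), np.concatenate(cols_i))),
            shape=(n, n),
        )
    else:
        graph = sparse.csr_matrix((n, n))

    src_idx = idx[open_src]
    dist = dijkstra(graph, directed=False, indices=src_idx, min_only=True)
    out = np.full((rows, cols), np.inf)
    out[open_mask] = dist
    out[open_src] = 0.0
    return AccumulatedCost(cost=out, sources=open_src)


def theoretical_max_cost(friction: FrictionSurface) -> float:
    """Worst-case accumulated cost: grid diagonal (in steps) × the highest
    open-cell friction. Serves as the X_t normaliser unless overridden."""
    open_cost = friction.cost[~friction.mask]
    if open_cost.size == 0:
        raise EmptyResultError("all cells are masked; no theoretical maximum")
    rows, cols = friction.cost.shape
    diag_steps = math.hypot(rows - 1, cols - 1)
    if diag_steps == 0:  # single-cell grid
        diag_steps = 1.0
    return float(diag_steps * open_cost.max())


def eci_b(
    x_i: float | np.ndarray,
    x_t: float,
    exponent: str = "ratio_cubed",
    strict: bool = False,
):
    """Per-area connectivity transform of accumulated cost.

    ``ratio_cubed`` (default): 10 − 9·[ln(1+X_i)/ln(1+X_t)]³.
    ``denominator_cubed``: 10 − 9·ln(1+X_i)/(3·ln(1+X_t)).
    X_i above X_t (including unreachable cells at +inf) is clamped to X_t
    with a warning, or rejected in strict mode.
    """
    if x_t <= 0:
        raise InvalidArgumentError("X_t must be > 0")
    x = np.asarray(x_i, dtype=float)
    if np.any(x < 0):
        raise InvalidArgumentError("X_i must be >= 0")
    if np.any(x > x_t):
        if strict:
            raise InvalidArgumentError("X_i exceeds X_t in strict mode")
        warnings.warn("X_i exceeds X_t; clamping to X_t", stacklevel=2)
        x = np.minimum(x, x_t)
    ratio = np.log1p(x) / np.log1p(x_t)
    if exponent == "ratio_cubed":
        val = 10.0 - 9.0 * ratio**3
    elif exponent == "denominator_cubed":
        val = 10.0 - 9.0 * np.log1p(x) / (3.0 * np.log1p(x_t))
    else:
        raise InvalidArgumentError(f"unknown exponent mode {exponent!r}")
    return float(val) if np.isscalar(x_i) else val


def eci_total(fields: dict[str, np.ndarray] | list[np.ndarray]) -> np.ndarray:
    """Total connectivity: per-cell arithmetic mean of the m per-area fields."""
    grids = list(fields.values()) if isinstance(fields, dict) else list(fields)
    if not grids:
        raise InvalidArgumentError("at least one per-area field is required")
    shape = grids[0].shape
    if any(g.shape != shape for g in grids):
        raise ValidationError("per-area ECI_b grids have mismatched shapes")
    stacked = np.stack(grids)
    with warnings.catch_warnings():
        # cells masked in every area (e.g. urban fabric) are NaN by design
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(stacked, axis=0)


def source_mask_for_area(
    raster: LandCoverRaster,
    legend: Legend,
    area: str,
    min_patch_cells: int = 1,
    connectivity: int = 8,
) -> np.ndarray:
    """Cells of functional area ``area`` in patches of at least ``min_patch_cells``."""
    codes = legend.classes_of_area(area)
    mask = np.isin(raster.grid, codes) & raster.valid_mask
    if min_patch_cells <= 1:
        return mask
    structure = np.ones((3, 3)) if connectivity == 8 else None
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = np.zeros_like(sizes, dtype=bool)
    keep[1:] = sizes[1:] >= min_patch_cells
    return keep[labels]


def rescale_to_index_range(field: np.ndarray, lo: float = 0.0, hi: float = 10.0) -> np.ndarray:
    """Min–max rescaling of a connectivity field onto the nominal index range."""
    finite = np.isfinite(field)
    if not finite.any():
        raise EmptyResultError("no finite connectivity values to rescale")
    fmin, fmax = field[finite].min(), field[finite].max()
    if fmax == fmin:
        out = np.full_like(field, (lo + hi) / 2.0)
        out[~finite] = np.nan
        return out
    out = lo + (hi - lo) * (field - fmin) / (fmax - fmin)
    out[~finite] = np.nan
    return out


@dataclass
class EciField:
    """Per-cell ECI_b fields, their mean, and the per-hexagon averages."""

    per_area: dict[str, np.ndarray]
    total: np.ndarray
    total_rescaled: np.ndarray
    x_t: dict[str, float]
    hexagon_mean: pd.Series | None = None


def compute_eci(
    raster: LandCoverRaster,
    legend: Legend,
    affinity: AffinityMatrix,
    barriers: BarrierSpec,
    composition: CoverComposition | None = None,
    areas: list[str] | None = None,
    connectivity: int = 8,
    base_cost: float = 1.0,
    barrier_affinity: float = 0.1,
    min_patch_cells: int = 1,
    x_t_override: float | None = None,
    exponent: str = "ratio_cubed",
) -> EciField:
    """End-to-end connectivity: friction → accumulated cost → ECI_b → mean ECI.

    Functional areas with no source cells in the raster are skipped (they
    contribute nothing to the mean, and m shrinks accordingly).
    """
    if areas is None:
        areas = list(affinity.areas)
    per_area: dict[str, np.ndarray] = {}
    x_ts: dict[str, float] = {}
    for area in areas:
        src = source_mask_for_area(
            raster, legend, area, min_patch_cells=min_patch_cells, connectivity=connectivity
        )
        if not src.any():
            continue
        friction = build_friction(
            raster, legend, affinity, barriers, area,
            base_cost=base_cost, barrier_affinity=barrier_affinity,
        )
        acc = accumulate_cost(friction, src, connectivity=connectivity)
        x_t = x_t_override if x_t_override is not None else theoretical_max_cost(friction)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # unreachable cells clamp to X_t by design
            field = eci_b(acc.cost, x_t, exponent=exponent)
        field = np.where(friction.mask, np.nan, field)
        per_area[area] = field
        x_ts[area] = x_t
    if not per_area:
        raise EmptyResultError("no functional area has source cells in this raster")
    total = eci_total(per_area)
    rescaled = rescale_to_index_range(total)
    hex_mean = composition.zonal_mean(total) if composition is not None else None
    return EciField(
        per_area=per_area,
        total=total,
        total_rescaled=rescaled,
        x_t=x_ts,
        hexagon_mean=hex_mean,
    )
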