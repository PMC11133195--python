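"""Synthetic study systems: landscapes, metabolism tables and expert panels.

The real study region is a tropical Andean valley-to-highland gradient:
industrial sugarcane monocultures with urban/industrial fabric on the
valley flats, smallholder agroforestry and agropastoral mosaics on the
mid-slopes, and dense forest, shrubland and paramo grassland in the
highlands. Its geodata is not deposited, so this module generates neutral
landscapes with that zonation structure — a modified-random-clusters
allocation within elevation-like bands, plus linear road/river features —
together with class NPP tables and 27-expert Likert panels whose latent
structure mirrors the qualitative contrasts the analysis assumes (natural
covers: high service supply and near-zero appropriation; monocultures and
built fabric: high appropriation and demand, low supply).

Every generator is a pure function of its scenario and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line as skline

from .connectivity import AffinityMatrix, BarrierClass, BarrierSpec
from .errors import InvalidArgumentError, ValidationError
from .hanpp import NPP_COLUMNS, NppTable
from .legend import DEFAULT_FUNCTIONAL_AREAS, Legend, LegendEntry
from .raster import LandCoverRaster
from .services import load_service_list

# ---------------------------------------------------------------------------
# Reference legend for the synthetic region: the 22 reclassified covers of
# the study legend, plus road infrastructure (23) used for linear barriers.

_L = LegendEntry
_LEGEND_ROWS = [
    _L(1, "Others (rocky outcrops, glaciers)", "forest_seminatural", "Total others", "rocky_sandy", "grassland_paramo"),
    _L(2, "Natural shrublands", "forest_seminatural", "Natural shrublands", "shrubland", "shrubland"),
    _L(3, "Natural grasslands (Paramo)", "forest_seminatural", "Natural grasslands (Paramo)", "grassland", "grassland_paramo"),
    _L(4, "Dense forest", "forest_seminatural", "Total primary forest", "forest", "forest"),
    _L(5, "Riparian forest", "forest_seminatural", "Total primary forest", "forest", "forest"),
    _L(6, "Secondary forest", "forest_seminatural", "Total secondary forest", "forest", "forest"),
    _L(7, "Secondary vegetation or in transition", "forest_seminatural", "Total secondary forest", "shrubland", "shrubland"),
    _L(8, "Permanent woody crops", "agricultural", "Total permanent crops", "heterogeneous_crops", "crops"),
    _L(9, "Sugarcane plantations", "agricultural", "Total permanent crops", "sugarcane", "sugarcane"),
    _L(10, "Pasture and forest mosaic", "agricultural", "Total agricultural mosaics", "heterogeneous_crops", "agroforestry_mosaic"),
    _L(11, "Cropland mosaic", "agricultural", "Total agricultural mosaics", "heterogeneous_crops", "agroforestry_mosaic"),
    _L(12, "Cropland and forest mosaic", "agricultural", "Total agricultural mosaics", "heterogeneous_crops", "agroforestry_mosaic"),
    _L(13, "Cropland, forest, and pasture mosaic", "agricultural", "Total agricultural mosaics", "heterogeneous_crops", "agroforestry_mosaic"),
    _L(14, "Cropland and pasture mosaic", "agricultural", "Total agricultural mosaics", "heterogeneous_crops", "agroforestry_mosaic"),
    _L(15, "Wooded pastures", "agricultural", "Total pastures", "pastures", "pastures"),
    _L(16, "Weeded pastures", "agricultural", "Total pastures", "pastures", "pastures"),
    _L(17, "Clean pastures", "agricultural", "Total pastures", "pastures", "pastures"),
    _L(18, "Timber plantations", "agricultural", "Timber plantations", "forest", "forest"),
    _L(19, "Rivers and natural water bodies", "water", "Total water", "water", "water"),
    _L(20, "Artificial water bodies", "water", "Total water", "water", "water"),
    _L(21, "Urban areas", "built", "Total urban and industrial areas", "no_habitat", None, True),
    _L(22, "Nude soils", "other", "Nude soils", "no_habitat", None, True),
    _L(23, "Road infrastructure", "built", "Total urban and industrial areas", "no_habitat", None, True),
]


def default_legend() -> Legend:
    """The 22-cover study legend (plus road infrastructure, code 23)."""
    return Legend(entries={e.code: e for e in _LEGEND_ROWS})


def default_affinity() -> AffinityMatrix:
    """Package-default ecological affinities between the functional areas.

    The study's coefficients were expert-elicited and never tabulated; these
    defaults are placeholders ordered by ecological proximity (forest–
    shrubland high, sugarcane low with everything, the hydrological network
    highly affine to forest) and are meant to be replaced by user config.
    """
    areas = list(DEFAULT_FUNCTIONAL_AREAS)
    rows = [
        # forest shrub  grass  mosaic crops  past   sugar  water
        [1.0, 0.8, 0.6, 0.6, 0.3, 0.3, 0.1, 0.8],  # forest
        [0.8, 1.0, 0.7, 0.6, 0.3, 0.4, 0.1, 0.6],  # shrubland
        [0.6, 0.7, 1.0, 0.5, 0.3, 0.5, 0.1, 0.5],  # grassland_paramo
        [0.6, 0.6, 0.5, 1.0, 0.6, 0.6, 0.2, 0.6],  # agroforestry_mosaic
        [0.3, 0.3, 0.3, 0.6, 1.0, 0.5, 0.3, 0.4],  # crops
        [0.3, 0.4, 0.5, 0.6, 0.5, 1.0, 0.3, 0.4],  # pastures
        [0.1, 0.1, 0.1, 0.2, 0.3, 0.3, 1.0, 0.2],  # sugarcane
        [0.8, 0.6, 0.5, 0.6, 0.4, 0.4, 0.2, 1.0],  # water
    ]
    return AffinityMatrix(table=pd.DataFrame(rows, index=areas, columns=areas))


def default_barriers() -> BarrierSpec:
    """Urban fabric is an impermeable barrier with a disturbance halo; roads
    are permeable but heavily penalised; degraded soil is inert filler."""
    return BarrierSpec(
        classes={
            21: BarrierClass(code=21, impact=5.0, halo_m=300.0, impermeable=True),
            22: BarrierClass(code=22, impact=0.0, halo_m=0.0, impermeable=False),
            23: BarrierClass(code=23, impact=5.0, halo_m=200.0, impermeable=False),
        }
    )


# ---------------------------------------------------------------------------
# Landscape generation


@dataclass(frozen=True)
class Band:
    """One elevation-like zone: a share of the grid's columns with its own
    class-probability mix."""

    name: str
    width_fraction: float
    class_mix: dict[int, float]


@dataclass(frozen=True)
class BarrierFeature:
    """A linear feature (road or river) rasterised over the allocation."""

    class_code: int
    start: tuple[int, int]  # (row, col)
    end: tuple[int, int]
    width_cells: int = 1


@dataclass(frozen=True)
class LandscapeScenario:
    shape: tuple[int, int] = (60, 100)
    cell_size: float = 100.0  # m
    bands: tuple[Band, ...] = ()
    clustering: float = 0.6
    barriers: tuple[BarrierFeature, ...] = ()
    seed: int = 1

    def band_columns(self) -> list[tuple[str, int, int]]:
        """(name, col_start, col_stop) per band, exhausting all columns."""
        _, cols = self.shape
        widths = [b.width_fraction for b in self.bands]
        total = sum(widths)
        counts = [int(math.floor(w / total * cols)) for w in widths]
        rema = [w / total * cols - c for w, c in zip(widths, counts)]
        for i in np.argsort(rema)[::-1][: cols - sum(counts)]:
            counts[int(i)] += 1
        out, start = [], 0
        for b, c in zip(self.bands, counts):
            out.append((b.name, start, start + c))
            start += c
        return out


def ucrv_like_scenario(seed: int = 1, shape: tuple[int, int] = (60, 100)) -> LandscapeScenario:
    """The default valley/slope/highland zonation: monoculture-dominated
    flats, heterogeneous mosaic mid-slopes, natural highlands, one river and
    two roads."""
    valley = Band(
        "valley", 0.40,
        {9: 0.75, 17: 0.06, 16: 0.03, 21: 0.06, 22: 0.02, 14: 0.04, 19: 0.02, 20: 0.01, 5: 0.01},
    )
    slope = Band(
        "slope", 0.35,
        {
            10: 0.10, 13: 0.12, 12: 0.07, 14: 0.05, 11: 0.02, 8: 0.02,
            15: 0.06, 16: 0.05, 17: 0.04,
            4: 0.08, 6: 0.07, 5: 0.02, 18: 0.03,
            7: 0.07, 2: 0.03, 3: 0.07,
            19: 0.02, 20: 0.01, 9: 0.04, 21: 0.02, 22: 0.01,
        },
    )
    highland = Band(
        "highland", 0.25,
        {4: 0.40, 3: 0.25, 2: 0.15, 7: 0.07, 6: 0.05, 18: 0.03, 1: 0.03, 19: 0.01, 17: 0.01},
    )
    rows, cols = shape
    return LandscapeScenario(
        shape=shape,
        bands=(valley, slope, highland),
        barriers=(
            BarrierFeature(19, (0, int(cols * 0.06)), (rows - 1, int(cols * 0.10)), 1),
            BarrierFeature(23, (0, int(cols * 0.20)), (rows - 1, int(cols * 0.20)), 1),
            BarrierFeature(23, (rows // 2, 0), (rows // 2, cols - 1), 1),
        ),
        seed=seed,
    )


def _integer_targets(probs: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder rounding of n·probs to integers summing to n."""
    raw = probs * n
    base = np.floor(raw).astype(int)
    rem = raw - base
    short = n - base.sum()
    order = np.argsort(rem)[::-1]
    base[order[:short]] += 1
    return base


def _grow_band(
    grid: np.ndarray,
    rows: int,
    col_lo: int,
    col_hi: int,
    codes: np.ndarray,
    targets: np.ndarray,
    clustering: float,
    rng: np.random.Generator,
) -> None:
    """Exact-count patch growth inside one band (modified random clusters).

    Each class gets round(N^(1-c)) seeded nuclei; classes then take turns
    claiming a random unassigned 4-neighbour of a random frontier cell until
    their quota is met, re-seeding when a frontier dies out.
    """
    band_cells = [(r, c) for c in range(col_lo, col_hi) for r in range(rows)]
    order = rng.permutation(len(band_cells))
    unassigned = {band_cells[i] for i in range(len(band_cells))}
    counts = np.zeros(len(codes), dtype=int)
    frontiers: list[list[tuple[int, int]]] = [[] for _ in codes]

    free = [band_cells[i] for i in order]
    pos = 0

    def take_seed() -> tuple[int, int] | None:
        nonlocal pos
        while pos < len(free):
            cell = free[pos]
            pos += 1
            if cell in unassigned:
                return cell
        return None

    for j, code in enumerate(codes):
        n_seeds = max(1, int(round(targets[j] ** (1.0 - clustering)))) if targets[j] else 0
        n_seeds = min(n_seeds, int(targets[j]))
        for _ in range(n_seeds):
            cell = take_seed()
            if cell is None:
                break
            unassigned.discard(cell)
            grid[cell] = code
            counts[j] += 1
            frontiers[j].append(cell)

    active = [j for j in range(len(codes)) if counts[j] < targets[j]]
    while active and unassigned:
        next_active = []
        progress = False
        for j in active:
            placed = False
            frontier = frontiers[j]
            while frontier and not placed:
                k = int(rng.integers(len(frontier)))
                r, c = frontier[k]
                nbrs = [
                    (r + dr, c + dc)
                    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1))
                    if 0 <= r + dr < rows and col_lo <= c + dc < col_hi
                    and (r + dr, c + dc) in unassigned
                ]
                if not nbrs:
                    frontier[k] = frontier[-1]  # dead frontier cell; retire it
                    frontier.pop()
                    continue
                cell = nbrs[int(rng.integers(len(nbrs)))]
                unassigned.discard(cell)
                grid[cell] = codes[j]
                counts[j] += 1
                frontier.append(cell)
                placed = True
            if not placed:
                cell = take_seed()  # frontier exhausted: re-seed from free cells
                if cell is not None:
                    unassigned.discard(cell)
                    grid[cell] = codes[j]
                    counts[j] += 1
                    frontiers[j].append(cell)
                    placed = True
            progress = progress or placed
            if counts[j] < targets[j]:
                next_active.append(j)
        if not progress:
            break
        active = next_active


def generate_landscape(scenario: LandscapeScenario) -> tuple[LandCoverRaster, Legend]:
    """Allocate the banded neutral landscape and rasterise its barriers.

    With clustering 0 the allocation is an independent cellwise multinomial
    draw per band; with clustering > 0 class cell counts match the band
    targets exactly (before barrier overwrite), grown from seeded nuclei.
    """
    legend = default_legend()
    rows, cols = scenario.shape
    if rows < 1 or cols < 1:
        raise InvalidArgumentError("scenario grid must have at least one cell")
    if not scenario.bands:
        raise InvalidArgumentError("scenario needs at least one band")
    if not 0.0 <= scenario.clustering <= 1.0:
        raise InvalidArgumentError("clustering must lie in [0, 1]")
    for b in scenario.bands:
        tot = sum(b.class_mix.values())
        if abs(tot - 1.0) > 1e-9:
            raise InvalidArgumentError(
                f"band {b.name!r}: class proportions sum to {tot}, expected 1"
            )
        unknown = [c for c in b.class_mix if c not in legend]
        if unknown:
            raise ValidationError(f"band {b.name!r}: unknown class codes {unknown}")

    rng = np.random.default_rng(scenario.seed)
    grid = np.full((rows, cols), -9999, dtype=np.int64)
    spans = scenario.band_columns()
    for band, (name, lo, hi) in zip(scenario.bands, spans):
        ncells = rows * (hi - lo)
        if ncells == 0:
            continue
        codes = np.array(sorted(band.class_mix), dtype=np.int64)
        probs = np.array([band.class_mix[int(c)] for c in codes], dtype=float)
        if ncells < np.count_nonzero(probs):
            raise InvalidArgumentError(
                f"band {name!r}: {ncells} cells cannot realise {np.count_nonzero(probs)} classes"
            )
        if scenario.clustering == 0.0:
            draws = rng.choice(codes, size=ncells, p=probs)
            grid[:, lo:hi] = draws.reshape(rows, hi - lo, order="F")
        else:
            targets = _integer_targets(probs, ncells)
            _grow_band(grid, rows, lo, hi, codes, targets, scenario.clustering, rng)

    for feat in scenario.barriers:
        rr, cc = skline(*feat.start, *feat.end)
        mask = np.zeros((rows, cols), dtype=bool)
        mask[np.clip(rr, 0, rows - 1), np.clip(cc, 0, cols - 1)] = True
        if feat.width_cells > 1:
            mask = ndimage.binary_dilation(mask, iterations=feat.width_cells - 1)
        grid[mask] = feat.class_code

    raster = LandCoverRaster(
        grid=grid, cell_size=scenario.cell_size, origin=(0.0, rows * scenario.cell_size)
    )
    return raster, legend


# ---------------------------------------------------------------------------
# Metabolism tables

# (npp0 range, NPP_act multiplier range on NPP_0, NPP_h multiplier range on NPP_act)
_NPP_RULES: dict[str, tuple[tuple[float, float], tuple[float, float], tuple[float, float]]] = {
    "natural": ((7.0, 13.0), (0.96, 1.00), (0.0, 0.0)),
    "sparse": ((0.5, 1.5), (0.96, 1.00), (0.0, 0.0)),  # water, rock, ice
    "sugarcane": ((9.0, 12.0), (1.15, 1.40), (0.65, 0.80)),
    "mosaic": ((8.0, 12.0), (0.75, 0.95), (0.25, 0.45)),
    "pasture": ((8.0, 12.0), (0.80, 1.00), (0.30, 0.50)),
    "plantation": ((8.0, 12.0), (0.85, 1.00), (0.20, 0.40)),
    "built": ((8.0, 12.0), (0.01, 0.05), (0.0, 0.0)),
    "degraded": ((6.0, 10.0), (0.05, 0.15), (0.0, 0.0)),
}


def _npp_rule(entry: LegendEntry) -> str:
    if entry.code == 9:
        return "sugarcane"
    if entry.code == 18:
        return "plantation"
    if entry.code == 22:
        return "degraded"
    if entry.typology == "built":
        return "built"
    if entry.typology == "water" or entry.habitat_category == "rocky_sandy":
        return "sparse"
    if entry.functional_area in ("agroforestry_mosaic", "crops"):
        return "mosaic"
    if entry.functional_area == "pastures":
        return "pasture"
    return "natural"


def generate_npp(legend: Legend, seed: int = 1) -> NppTable:
    """Draw a per-class NPP table (t C/ha/yr) consistent with the class's
    land-use intensity: natural covers appropriate almost nothing, built
    fabric almost everything, monocultures harvest most of an irrigation-
    boosted production."""
    if not legend.codes:
        raise InvalidArgumentError("legend has no classes")
    rng = np.random.default_rng(seed)
    rows = []
    for code in legend.codes:
        rule = _NPP_RULES[_npp_rule(legend[code])]
        npp0 = rng.uniform(*rule[0])
        act = npp0 * rng.uniform(*rule[1])
        h = act * rng.uniform(*rule[2])
        rows.append({"class": code, "npp0_tC_ha": npp0, "nppact_tC_ha": act, "npph_tC_ha": h})
    df = pd.DataFrame(rows).set_index("class")[NPP_COLUMNS]
    return NppTable(table=df)


# ---------------------------------------------------------------------------
# Expert panels

# latent (supply, demand) per section, keyed by a cover family
_LATENTS: dict[str, dict[str, tuple[float, float]]] = {
    "forest": {"provisioning": (3, 0), "regulation_support": (5, 0), "cultural": (4, 1)},
    "shrubland": {"provisioning": (2, 0), "regulation_support": (4, 0), "cultural": (3, 1)},
    "paramo": {"provisioning": (3, 0), "regulation_support": (5, 0), "cultural": (4, 1)},
    "sparse": {"provisioning": (1, 0), "regulation_support": (2, 0), "cultural": (3, 0)},
    "water": {"provisioning": (4, 1), "regulation_support": (4, 1), "cultural": (4, 1)},
    "mosaic": {"provisioning": (4, 2), "regulation_support": (3, 2), "cultural": (3, 1)},
    "pasture": {"provisioning": (3, 2), "regulation_support": (2, 2), "cultural": (2, 1)},
    "sugarcane": {"provisioning": (2, 4), "regulation_support": (1, 3), "cultural": (1, 1)},
    "built": {"provisioning": (0, 5), "regulation_support": (0, 4), "cultural": (1, 4)},
    "degraded": {"provisioning": (0, 1), "regulation_support": (0, 1), "cultural": (0, 0)},
}


def _latent_family(entry: LegendEntry) -> str:
    if entry.code == 3:
        return "paramo"
    if entry.code == 9:
        return "sugarcane"
    if entry.code == 22:
        return "degraded"
    if entry.typology == "built":
        return "built"
    if entry.typology == "water":
        return "water"
    if entry.habitat_category == "rocky_sandy":
        return "sparse"
    if entry.functional_area in ("agroforestry_mosaic", "crops"):
        return "mosaic"
    if entry.functional_area == "pastures":
        return "pasture"
    if entry.functional_area == "shrubland":
        return "shrubland"
    return "forest"


def default_latent_matrices(
    legend: Legend, services: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Latent supply/demand matrices (service × cover code) on the 0–5 scale."""
    if services is None:
        services = load_service_list()
    covers = legend.codes
    sup = pd.DataFrame(index=services["code"], columns=covers, dtype=float)
    dem = pd.DataFrame(index=services["code"], columns=covers, dtype=float)
    sections = services.set_index("code")["section"]
    for cover in covers:
        fam = _LATENTS[_latent_family(legend[cover])]
        for code in sup.index:
            s, d = fam[sections[code]]
            sup.loc[code, cover] = s
            dem.loc[code, cover] = d
    return sup, dem


@dataclass(frozen=True)
class PanelScenario:
    n_experts: int = 27
    noise_p: float = 0.2  # probability a score is perturbed by ±1
    seed: int = 1
    latent_supply: pd.DataFrame | None = None
    latent_demand: pd.DataFrame | None = None


def generate_expert_panel(
    scenario: PanelScenario,
    legend: Legend | None = None,
    services: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Simulate the Likert elicitation: each expert scores every (service,
    cover) pair with the rounded latent value, perturbed by ±1 with
    probability ``noise_p`` and clipped to the 0–5 scale."""
    if services is None:
        services = load_service_list()
    if scenario.latent_supply is not None:
        sup, dem = scenario.latent_supply, scenario.latent_demand
        if dem is None:
            raise InvalidArgumentError("latent_supply without latent_demand")
    else:
        if legend is None:
            legend = default_legend()
        sup, dem = default_latent_matrices(legend, services)
    for name, m in (("supply", sup), ("demand", dem)):
        vals = m.to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 5)):
            raise InvalidArgumentError(f"latent {name} values outside [0, 5]")
    if not 0.0 <= scenario.noise_p <= 1.0:
        raise InvalidArgumentError("noise_p must lie in [0, 1]")

    sections = services.set_index("code")["section"]
    rng = np.random.default_rng(scenario.seed)
    n_cells = sup.shape[0] * sup.shape[1]
    records = []
    base_s = np.rint(sup.to_numpy(dtype=float))
    base_d = np.rint(dem.to_numpy(dtype=float))
    for expert in range(1, scenario.n_experts + 1):
        for mat, base in (("supply", base_s), ("demand", base_d)):
            flip = rng.random((sup.shape[0], sup.shape[1])) < scenario.noise_p
            sign = rng.choice([-1, 1], size=flip.shape)
            vals = np.clip(base + flip * sign, 0, 5).astype(int)
            if mat == "supply":
                s_vals = vals
            else:
                d_vals = vals
        for i, code in enumerate(sup.index):
            for jj, cover in enumerate(sup.columns):
                records.append(
                    {
                        "expert_id": expert,
                        "service_code": code,
                        "section": sections[code],
                        "cover": cover,
                        "supply": int(s_vals[i, jj]),
                        "demand": int(d_vals[i, jj]),
                    }
                )
    return pd.DataFrame.from_records(records)
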