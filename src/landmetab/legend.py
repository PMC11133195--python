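"""Land-cover legends: class codes, typologies, reclassification groups.

A :class:`Legend` maps integer raster codes to named land-cover classes and
carries the three groupings the downstream metrics need:

* ``typology`` — broad accounting group (forest/seminatural, agricultural,
  water, built, other) used for area roll-ups and the natural-cover test;
* ``habitat_category`` — the habitat grouping the Shannon heterogeneity
  index runs over (potential-habitat covers plus one "no habitat" bucket);
* ``functional_area`` — the connectivity source/target class (forest,
  shrubland, grassland/paramo, agroforestry mosaic, crops, pastures,
  sugarcane, plus the hydrological network), or ``None`` for covers that act
  only as anthropogenic barriers (``barrier_flag``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ValidationError

TYPOLOGIES = ("forest_seminatural", "agricultural", "water", "built", "other")

#: The seven terrestrial connectivity classes plus the hydrological network,
#: which is handled as its own functional area with high affinity to forest.
DEFAULT_FUNCTIONAL_AREAS = (
    "forest",
    "shrubland",
    "grassland_paramo",
    "agroforestry_mosaic",
    "crops",
    "pastures",
    "sugarcane",
    "water",
)


@dataclass(frozen=True)
class LegendEntry:
    code: int
    name: str
    typology: str
    reclass_group: str
    habitat_category: str | None = None
    functional_area: str | None = None
    barrier_flag: bool = False


@dataclass
class Legend:
    """Validated collection of :class:`LegendEntry` keyed by class code."""

    entries: dict[int, LegendEntry]
    nodata: int = -9999
    functional_areas: tuple[str, ...] = DEFAULT_FUNCTIONAL_AREAS

    def __post_init__(self) -> None:
        problems: list[str] = []
        fa_set = set(self.functional_areas)
        for code, e in self.entries.items():
            if code != e.code:
                problems.append(f"entry key {code} != entry code {e.code}")
            if e.typology not in TYPOLOGIES:
                problems.append(f"class {code} ({e.name}): unknown typology {e.typology!r}")
            if e.functional_area is not None and e.functional_area not in fa_set:
                problems.append(
                    f"class {code} ({e.name}): functional_area {e.functional_area!r} "
                    f"not in configured set {sorted(fa_set)}"
                )
        if self.nodata in self.entries:
            problems.append(f"nodata code {self.nodata} collides with a legend class")
        if problems:
            raise ValidationError("invalid legend", problems)

    @property
    def codes(self) -> list[int]:
        return sorted(self.entries)

    def __contains__(self, code: int) -> bool:
        return code in self.entries

    def __getitem__(self, code: int) -> LegendEntry:
        return self.entries[code]

    def habitat_categories(self) -> list[str]:
        """Distinct habitat categories, in first-appearance order of sorted codes."""
        seen: dict[str, None] = {}
        for code in self.codes:
            cat = self.entries[code].habitat_category
            if cat is not None:
                seen.setdefault(cat, None)
        return list(seen)

    def classes_of_area(self, functional_area: str) -> list[int]:
        return [c for c in self.codes if self.entries[c].functional_area == functional_area]

    def barrier_classes(self) -> list[int]:
        return [c for c in self.codes if self.entries[c].barrier_flag]

    def natural_codes(self) -> list[int]:
        """Codes counted as natural cover (forest/seminatural and water typologies)."""
        return [
            c
            for c in self.codes
            if self.entries[c].typology in ("forest_seminatural", "water")
        ]


_HEADER = [
    "code",
    "name",
    "typology",
    "reclass_group",
    "habitat_category",
    "functional_area",
    "barrier_flag",
]


def read_legend(
    path: str | Path,
    nodata: int = -9999,
    functional_areas: tuple[str, ...] = DEFAULT_FUNCTIONAL_AREAS,
) -> Legend:
    """Read a legend CSV with columns ``code,name,typology,reclass_group,
    habitat_category,functional_area,barrier_flag``.

    Empty ``habitat_category``/``functional_area`` fields become ``None``;
    ``barrier_flag`` accepts 0/1/true/false.
    """
    path = Path(path)
    entries: dict[int, LegendEntry] = {}
    problems: list[str] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _HEADER if c not in (reader.fieldnames or [])]
        if missing:
            raise ValidationError(f"legend {path}: missing columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                code = int(row["code"])
            except ValueError:
                problems.append(f"{path}:{lineno}: non-integer code {row['code']!r}")
                continue
            if code in entries:
                problems.append(f"{path}:{lineno}: duplicate code {code}")
                continue
            entries[code] = LegendEntry(
                code=code,
                name=row["name"].strip(),
                typology=row["typology"].strip(),
                reclass_group=row["reclass_group"].strip(),
                habitat_category=row["habitat_category"].strip() or None,
                functional_area=row["functional_area"].strip() or None,
                barrier_flag=str(row["barrier_flag"]).strip().lower() in ("1", "true", "yes"),
            )
    if problems:
        raise ValidationError(f"invalid legend file {path}", problems)
    return Legend(entries=entries, nodata=nodata, functional_areas=functional_areas)


def write_legend(legend: Legend, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for code in legend.codes:
            e = legend.entries[code]
            writer.writerow(
                [
                    e.code,
                    e.name,
                    e.typology,
                    e.reclass_group,
                    e.habitat_category or "",
                    e.functional_area or "",
                    int(e.barrier_flag),
                ]
            )
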