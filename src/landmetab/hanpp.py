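"""Human appropriation of net primary production (HANPP) accounting.

Per land-cover class, with all NPP flows in t C/ha/yr:

    ΔNPP_Lu   = NPP_0 − NPP_act        (production foregone to land use)
    HANPP     = ΔNPP_Lu + NPP_h        (foregone plus harvested)
    HANPP_%   = 100 · HANPP / NPP_0    (share of potential production)

ΔNPP_Lu may be negative where management raises production above the
potential baseline (e.g. irrigated cropland); the raw percent is preserved
and a [0, 100]-clamped variant is carried for the disturbance composite,
which needs 1 − HANPP/100 to stay within [0, 1]. Hexagon values are the
cover-proportion-weighted averages of class values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .hexgrid import CoverComposition

logger = logging.getLogger(__name__)

NPP_COLUMNS = ["npp0_tC_ha", "nppact_tC_ha", "npph_tC_ha"]


@dataclass
class NppTable:
    """Per-class potential, actual and harvested NPP (t C/ha/yr).

    ``table`` is indexed by class code with columns ``npp0_tC_ha``,
    ``nppact_tC_ha``, ``npph_tC_ha``. Harvest above actual production is a
    physical impossibility and is rejected at load.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in NPP_COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"NPP table missing columns {missing}")
        problems: list[str] = []
        for code, row in t.iterrows():
            if row["npp0_tC_ha"] <= 0:
                problems.append(f"class {code}: NPP_0 = {row['npp0_tC_ha']} must be > 0")
            if row["nppact_tC_ha"] < 0 or row["npph_tC_ha"] < 0:
                problems.append(f"class {code}: negative NPP_act or NPP_h")
            if row["npph_tC_ha"] > row["nppact_tC_ha"] + 1e-12:
                problems.append(
                    f"class {code}: harvested NPP {row['npph_tC_ha']} exceeds actual "
                    f"{row['nppact_tC_ha']}"
                )
        if t.index.has_duplicates:
            problems.append("duplicate class codes")
        if problems:
            raise ValidationError("invalid NPP table", problems)

    @property
    def classes(self) -> list[int]:
        return list(self.table.index)


def read_npp(path: str | Path) -> NppTable:
    """CSV with columns ``class,npp0_tC_ha,nppact_tC_ha,npph_tC_ha``."""
    df = pd.read_csv(path)
    if "class" not in df.columns:
        raise ValidationError(f"NPP table {path}: missing 'class' column")
    df["class"] = df["class"].astype(int)
    return NppTable(table=df.set_index("class"))


def compute_hanpp_class(npp: NppTable) -> pd.DataFrame:
    """Class-level HANPP table.

    Columns: ``delta_npp_lu``, ``hanpp_tC_ha``, ``hanpp_pct_raw`` and the
    [0, 100]-clamped ``hanpp_pct``. Classes whose raw percent falls outside
    [0, 100] are logged when clamped.
    """
    t = npp.table
    out = pd.DataFrame(index=t.index)
    out["delta_npp_lu"] = t["npp0_tC_ha"] - t["nppact_tC_ha"]
    out["hanpp_tC_ha"] = out["delta_npp_lu"] + t["npph_tC_ha"]
    out["hanpp_pct_raw"] = 100.0 * out["hanpp_tC_ha"] / t["npp0_tC_ha"]
    out["hanpp_pct"] = out["hanpp_pct_raw"].clip(0.0, 100.0)
    clamped = out.index[out["hanpp_pct_raw"] != out["hanpp_pct"]]
    for code in clamped:
        logger.info(
            "HANPP%% of class %s clamped from %.2f to [0, 100]",
            code,
            out.loc[code, "hanpp_pct_raw"],
        )
    return out


def hanpp_hex(composition: CoverComposition, hanpp: pd.DataFrame) -> pd.DataFrame:
    """Cover-weighted hexagon HANPP: Σ_i w_i · HANPP_i with w_i = P_ij.

    Excluded hexagons are dropped. Every class with positive proportion in a
    retained hexagon must have a HANPP row.
    """
    props = composition.proportions.loc[composition.included_ids]
    used = props.columns[(props > 0).any(axis=0)]
    missing = [int(c) for c in used if c not in hanpp.index]
    if missing:
        raise ValidationError(
            "classes present in hexagons but absent from the HANPP table",
            [f"class {c}" for c in missing],
        )
    w = props[used].to_numpy()
    out = pd.DataFrame(index=props.index)
    for col in ("hanpp_tC_ha", "hanpp_pct_raw", "hanpp_pct"):
        vals = hanpp.loc[[int(c) for c in used], col].to_numpy()
        out[col] = w @ vals
    return out
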