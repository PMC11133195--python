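"""Expert-panel ecosystem-service assessment.

A panel of experts scores, on a six-class Likert scale (0 = not relevant …
5 = very high), the capacity of each land cover to *supply* and to *demand*
each of 21 CICES-derived ecosystem services grouped into three sections
(provisioning, regulation & support, cultural). Responses are averaged into
supply and demand matrices, from which two per-cover criteria follow:

* capacity  ESC_i = mean over services of (supply − demand) ∈ [−5, 5];
* multifunctionality MF_i ∈ [0, 5]: the breadth of services offered,
  5 × mean over the three sections of the fraction of section services
  whose mean supply reaches a relevance threshold (default 3, "medium").

Hexagon values are cover-proportion-weighted sums: ESC_j = Σ ESC_i·P_ij and
MF_j = Σ MF_i·P_ij.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    InvalidArgumentError,
    InvalidConfigurationError,
    ValidationError,
)
from .hexgrid import CoverComposition

SECTIONS = ("provisioning", "regulation_support", "cultural")

RESPONSE_COLUMNS = ["expert_id", "service_code", "section", "cover", "supply", "demand"]


def load_service_list(path: str | Path | None = None) -> pd.DataFrame:
    """The 21-service CICES catalogue (columns section, division, code, group)."""
    if path is not None:
        df = pd.read_csv(path)
    else:
        with resources.files("landmetab.data").joinpath("cices_services.csv").open() as fh:
            df = pd.read_csv(fh)
    unknown = set(df["section"]) - set(SECTIONS)
    if unknown:
        raise ValidationError(f"unknown service sections {sorted(unknown)}")
    return df


def validate_responses(responses: pd.DataFrame) -> pd.DataFrame:
    """Check the Likert response table: columns, score range, uniqueness."""
    missing = [c for c in RESPONSE_COLUMNS if c not in responses.columns]
    if missing:
        raise ValidationError(f"expert responses missing columns {missing}")
    problems: list[str] = []
    for col in ("supply", "demand"):
        vals = responses[col]
        bad = responses.loc[~vals.isin(range(6)), col]
        if len(bad):
            problems.append(
                f"{col} scores outside the 0-5 Likert scale: {sorted(bad.unique())[:5]}"
            )
    dup = responses.duplicated(subset=["expert_id", "service_code", "cover"])
    if dup.any():
        problems.append(f"{int(dup.sum())} duplicate (expert, service, cover) responses")
    if problems:
        raise ValidationError("invalid expert response table", problems)
    return responses


def read_responses(path: str | Path) -> pd.DataFrame:
    """CSV with columns ``expert_id,service_code,section,cover,supply,demand``."""
    return validate_responses(pd.read_csv(path))


@dataclass
class ServiceMatrix:
    """Panel-averaged supply and demand per (service, cover), with counts."""

    supply: pd.DataFrame  # services x covers, values in [0, 5]
    demand: pd.DataFrame
    count: pd.DataFrame
    sections: pd.Series  # service_code -> section

    def __post_init__(self) -> None:
        for name, m in (("supply", self.supply), ("demand", self.demand)):
            vals = m.to_numpy(dtype=float)
            if np.any((vals < 0) | (vals > 5)):
                raise ValidationError(f"{name} means outside [0, 5]")

    @property
    def covers(self) -> list:
        return list(self.supply.columns)


def aggregate_panel(responses: pd.DataFrame) -> ServiceMatrix:
    """Average the experts' scores into supply and demand matrices."""
    responses = validate_responses(responses)
    g = responses.groupby(["service_code", "cover"])
    supply = g["supply"].mean().unstack("cover")
    demand = g["demand"].mean().unstack("cover")
    count = g["supply"].size().unstack("cover").fillna(0).astype(int)
    sections = responses.groupby("service_code")["section"].first()
    return ServiceMatrix(
        supply=supply.fillna(0.0) if supply.isna().any().any() else supply,
        demand=demand.fillna(0.0) if demand.isna().any().any() else demand,
        count=count,
        sections=sections,
    )


def capacity(supply, demand):
    """Service capacity C = supply − demand, on the [−5, 5] scale."""
    s = np.asarray(supply, dtype=float)
    d = np.asarray(demand, dtype=float)
    if np.any((s < 0) | (s > 5)) or np.any((d < 0) | (d > 5)):
        raise InvalidArgumentError("supply and demand scores must lie in [0, 5]")
    out = s - d
    return float(out) if np.isscalar(supply) and np.isscalar(demand) else out


def cover_capacity(matrix: ServiceMatrix, aggregate: str = "mean") -> pd.Series:
    """ESC_i per cover: capacity aggregated over the services.

    The mean (default) preserves the [−5, 5] range of the capacity scale;
    ``aggregate="sum"`` is available but leaves the printed range.
    """
    if matrix.supply.empty or not len(matrix.covers):
        raise ValidationError("service matrix has no covers")
    cap = pd.DataFrame(
        capacity(matrix.supply.to_numpy(), matrix.demand.to_numpy()),
        index=matrix.supply.index,
        columns=matrix.supply.columns,
    )
    if aggregate == "mean":
        return cap.mean(axis=0).rename("esc")
    if aggregate == "sum":
        return cap.sum(axis=0).rename("esc")
    raise InvalidArgumentError(f"unknown aggregate {aggregate!r}")


def cover_multifunctionality(
    matrix: ServiceMatrix,
    threshold: float = 3.0,
) -> pd.Series:
    """MF_i per cover: breadth of services offered across the three sections.

    MF_i = 5 · (1/3) Σ_sections (#{section services with mean supply ≥
    threshold} / #section services). A cover supplying every service of
    every section scores 5; one supplying none scores 0.
    """
    by_section = matrix.sections.reindex(matrix.supply.index)
    if by_section.isna().any():
        raise ValidationError("services without a section in the response table")
    counts = by_section.value_counts()
    empty = [s for s in SECTIONS if counts.get(s, 0) == 0]
    if empty:
        raise InvalidConfigurationError(f"sections with no services: {empty}")
    frac = pd.DataFrame(index=list(SECTIONS), columns=matrix.supply.columns, dtype=float)
    offered = matrix.supply >= threshold
    for section in SECTIONS:
        codes = by_section.index[by_section == section]
        frac.loc[section] = offered.loc[codes].mean(axis=0)
    return (5.0 * frac.mean(axis=0)).rename("mf")


def esc_hex(
    composition: CoverComposition,
    esc_i: pd.Series,
    mf_i: pd.Series | None = None,
    cover_codes: dict | None = None,
) -> pd.DataFrame:
    """Cover-weighted hexagon scores ESC_j (and MF_j when supplied).

    ``cover_codes`` maps the score index (cover names) to raster class codes
    when the two differ; by default the score index is taken to be codes.
    """
    props = composition.proportions.loc[composition.included_ids]
    if cover_codes is not None:
        esc_i = esc_i.rename(index=cover_codes)
        if mf_i is not None:
            mf_i = mf_i.rename(index=cover_codes)
    used = props.columns[(props > 0).any(axis=0)]
    missing = [c for c in used if c not in esc_i.index]
    if missing:
        raise ValidationError(
            "covers present in hexagons lack service scores",
            [f"cover {c}" for c in missing],
        )
    w = props[used].to_numpy()
    out = pd.DataFrame(index=props.index)
    out["esc"] = w @ esc_i.loc[list(used)].to_numpy(dtype=float)
    if mf_i is not None:
        miss2 = [c for c in used if c not in mf_i.index]
        if miss2:
            raise ValidationError(
                "covers present in hexagons lack multifunctionality scores",
                [f"cover {c}" for c in miss2],
            )
        out["mf"] = w @ mf_i.loc[list(used)].to_numpy(dtype=float)
    return out
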