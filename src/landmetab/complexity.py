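"""Landscape heterogeneity, combined complexity and the disturbance composite.

Heterogeneity is normalised Shannon entropy over habitat categories,

    H' = −Σ_j p_j ln p_j / ln J ∈ [0, 1],

with J the number of configured categories (potential-habitat covers plus a
single "no habitat" bucket grouping urban/industrial fabric, degraded land
and road infrastructure). Normalisation makes the value log-base invariant.

The combined complexity term blends pattern and process,

    Le = (a·H' + b·ECI/10) / (a + b) ∈ [0, 1],

and the intermediate-disturbance composite discounts it by the share of
primary production appropriated by society:

    IDC = Le · (1 − HANPP/100) ∈ [0, 1].

High IDC marks heterogeneous, well-connected landscapes under intermediate
human appropriation — the mosaic configurations; very low IDC marks
industrialised monoculture/urban landscapes (anthropic); homogeneous
little-disturbed covers sit in between (natural).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    InvalidArgumentError,
    InvalidConfigurationError,
)
from .hexgrid import CoverComposition
from .legend import Legend


def shannon(
    composition: CoverComposition,
    legend: Legend,
    categories: list[str] | None = None,
) -> pd.Series:
    """Normalised Shannon heterogeneity H' per hexagon.

    Class proportions are first grouped into habitat categories via the
    legend; classes without a habitat category are ignored (and the
    remaining proportions renormalised). ``categories`` fixes J explicitly;
    by default J is the number of distinct categories in the legend.
    """
    if categories is None:
        categories = legend.habitat_categories()
    j = len(categories)
    if j < 2:
        raise InvalidConfigurationError(
            f"Shannon index needs at least 2 habitat categories, got {j}"
        )
    props = composition.proportions
    grouped = pd.DataFrame(0.0, index=props.index, columns=categories)
    for code in props.columns:
        cat = legend[int(code)].habitat_category if int(code) in legend else None
        if cat is not None and cat in grouped.columns:
            grouped[cat] += props[code]
    totals = grouped.sum(axis=1)
    p = grouped.div(totals.where(totals > 0), axis=0).fillna(0.0).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h = -plogp.sum(axis=1) / np.log(j)
    return pd.Series(np.clip(h, 0.0, 1.0) + 0.0, index=props.index, name="hprime")


def landscape_complexity(hprime, eci, a: float = 1.0, b: float = 1.0):
    """Le = (a·H' + b·ECI/10)/(a + b): weighted blend of pattern and process."""
    if a <= 0 or b <= 0:
        raise InvalidArgumentError("weights a and b must be > 0")
    h = np.asarray(hprime, dtype=float)
    e = np.asarray(eci, dtype=float)
    if np.any((h < -1e-9) | (h > 1 + 1e-9)):
        raise InvalidArgumentError("H' must lie in [0, 1]")
    if np.any((e < -1e-9) | (e > 10 + 1e-9)):
        raise InvalidArgumentError("ECI must lie in [0, 10]")
    le = (a * h + b * e / 10.0) / (a + b)
    if isinstance(hprime, pd.Series):
        return pd.Series(le, index=hprime.index, name="le")
    return float(le) if np.isscalar(hprime) else le


def variance_equalizing_weights(hprime: pd.Series, eci: pd.Series) -> tuple[float, float]:
    """Data-driven (a, b): inverse across-hexagon standard deviations of H'
    and ECI/10, so both terms contribute equal variance to Le."""
    sh = float(np.std(np.asarray(hprime, dtype=float)))
    se = float(np.std(np.asarray(eci, dtype=float) / 10.0))
    if sh <= 0 or se <= 0:
        raise InvalidArgumentError(
            "variance-equalizing weights need positive spread in both H' and ECI"
        )
    return 1.0 / sh, 1.0 / se


def idc(le, hanpp_pct):
    """IDC = Le · (1 − HANPP%/100). Inputs must already be in range (the
    HANPP clamp happens upstream, in the metabolism stage)."""
    l = np.asarray(le, dtype=float)
    h = np.asarray(hanpp_pct, dtype=float)
    if np.any((l < -1e-9) | (l > 1 + 1e-9)):
        raise InvalidArgumentError("Le must lie in [0, 1]")
    if np.any((h < -1e-9) | (h > 100 + 1e-9)):
        raise InvalidArgumentError("HANPP percent must lie in [0, 100]")
    out = l * (1.0 - h / 100.0)
    if isinstance(le, pd.Series):
        return pd.Series(out, index=le.index, name="idc")
    return float(out) if np.isscalar(le) else out


@dataclass(frozen=True)
class ConfigurationBands:
    """IDC bands for the landscape-metabolic configuration classes.

    Only the anthropic band is reported by the study (0.05 < IDC < 0.3);
    the natural band and the mosaic threshold are package defaults, clearly
    configurable. Natural additionally requires natural covers to dominate.
    """

    anthropic: tuple[float, float] = (0.05, 0.3)
    natural: tuple[float, float] = (0.3, 0.5)
    mosaic_min: float = 0.5
    natural_dominance: float = 0.5

    def __post_init__(self) -> None:
        a0, a1 = self.anthropic
        n0, n1 = self.natural
        if not (0 <= a0 < a1 and n0 < n1 and 0 < self.mosaic_min <= 1):
            raise InvalidConfigurationError("malformed configuration bands")
        if a1 > n0 or n1 > self.mosaic_min:
            raise InvalidConfigurationError(
                f"configuration bands overlap: anthropic {self.anthropic}, "
                f"natural {self.natural}, mosaic >= {self.mosaic_min}"
            )


def classify_configuration(
    idc_values: pd.Series,
    natural_fraction: pd.Series,
    bands: ConfigurationBands = ConfigurationBands(),
) -> pd.Series:
    """Label hexagons anthropic / natural / mosaic / unclassified.

    anthropic: IDC strictly inside the low band; natural: IDC in the
    low-to-moderate band AND natural covers above the dominance share;
    mosaic: IDC at or above the high threshold.
    """
    a0, a1 = bands.anthropic
    n0, n1 = bands.natural
    v = idc_values.astype(float)
    nf = natural_fraction.reindex(v.index).fillna(0.0)
    labels = pd.Series("unclassified", index=v.index, name="config_label")
    labels[(v > a0) & (v < a1)] = "anthropic"
    labels[(v >= n0) & (v < n1) & (nf > bands.natural_dominance)] = "natural"
    labels[v >= bands.mosaic_min] = "mosaic"
    return labels
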