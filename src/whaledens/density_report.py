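"""Satellite-side density assembly and ship-vs-satellite comparison.

Satellite densities are snapshot counts per scanned image area (overlap
regions counted, since each image is searched independently), with a
binomial classification CV; availability adjustment divides by â and adds
its CV in quadrature.  Ratios between platforms are computed from
unrounded intermediates and rounded only for display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from whaledens.availability import AvailabilityEstimate, adjust_density
from whaledens.distance_sampling import DensityEstimate
from whaledens.errors import ValidationError
from whaledens.foi_scoring import ClassifiedCounts, proportion_se

CLASS_SELECTORS = ("definite", "probable", "unclassified", "definite+probable")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, the convention used in tabular output."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def _selected_count(counts: ClassifiedCounts, selector: str) -> int:
    if selector == "definite":
        return counts.n_definite
    if selector == "probable":
        return counts.n_probable
    if selector == "unclassified":
        return counts.n_unclassified
    if selector == "definite+probable":
        return counts.n_definite_probable
    raise ValidationError(f"unknown class selector {selector!r}")


def satellite_density(
    counts: ClassifiedCounts,
    area: float,
    class_selector: str = "definite+probable",
    stratum: str = "whole",
) -> DensityEstimate:
    """Snapshot density of one FOI class: count / area.

    The CV is the binomial CV of the class proportion, SE/p with n the
    total number of FOIs — classification uncertainty is the only
    stochastic component of the raw count.
    """
    if area <= 0:
        raise ValidationError("area must be > 0")
    k = _selected_count(counts, class_selector)
    n = counts.n_total
    if k > 0 and n > 0:
        p, se = proportion_se(k, n)
        cv = se / p
    else:
        cv = 0.0
    return DensityEstimate(
        density=k / area,
        cv=float(cv),
        platform="satellite",
        stratum=stratum,
        adjusted=False,
        components={"classification": float(cv)},
        foi_class=class_selector,
    )


@dataclass
class ComparisonReport:
    """Ship-vs-satellite comparison: per-class density table and ratios."""

    table: pd.DataFrame          # class/stratum rows, raw + adjusted densities
    ratios: dict[str, float]     # label -> ship density / adjusted satellite density
    ship: DensityEstimate
    availability: AvailabilityEstimate

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        for col in ("density", "cv", "density_adjusted", "cv_adjusted"):
            out[col] = out[col].map(lambda v: round_half_up(v, 2))
        out.to_csv(path, index=False)

    def ratios_text(self) -> str:
        lines = [
            f"ship density / adjusted satellite density ({name}): {ratio:.1f}"
            if math.isfinite(ratio)
            else f"ship density / adjusted satellite density ({name}): infinite"
            for name, ratio in self.ratios.items()
        ]
        return "\n".join(lines) + "\n"


def build_comparison(
    ship: DensityEstimate,
    satellite: Sequence[DensityEstimate],
    availability: AvailabilityEstimate,
) -> ComparisonReport:
    """Assemble the per-class density table and ship/satellite ratios.

    Every satellite row is availability-adjusted (density/â, CVs in
    quadrature); ratios are formed from the unrounded adjusted values for
    each definite+probable row.  A zero satellite density yields an
    infinite ratio, flagged as such in the text rendering.
    """
    if not satellite:
        raise ValidationError("need at least one satellite estimate")
    rows = []
    ratios: dict[str, float] = {}
    for est in satellite:
        adj = adjust_density(est, availability)
        rows.append(
            {
                "class": est.foi_class or "definite+probable",
                "stratum": est.stratum,
                "density": est.density,
                "cv": est.cv,
                "density_adjusted": adj.density,
                "cv_adjusted": adj.cv,
            }
        )
        name = f"{rows[-1]['class']}/{est.stratum}"
        ratios[name] = ship.density / adj.density if adj.density > 0 else math.inf
    table = pd.DataFrame(rows)
    return ComparisonReport(table=table, ratios=ratios, ship=ship, availability=availability)
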