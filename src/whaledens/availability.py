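"""Surface availability from archival tag depth records.

An overhead (satellite or aerial) platform samples the sea surface
instantaneously, so only whales shallower than a detectability threshold —
1 m by default, a deliberately conservative choice — are countable.  Each
suction-cup deployment yields daylight seconds above (E_s) and below (E_d)
the threshold; availability â is the pooled, tag-duration-weighted
proportion of time at the surface,

    â = Σ E_s / Σ T,   T = E_s + E_d,

and a raw snapshot density d̂ is corrected to d̂/â with CVs combined in
quadrature.  The CV of â is the between-tag dispersion of the per-tag
proportions (duration-weighted, with a reliability-weight correction)
relative to â — surface behaviour varies strongly between individuals, and
that variability, not the sampling error of the mean, dominates the
uncertainty of the correction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from whaledens.distance_sampling import DensityEstimate
from whaledens.errors import ValidationError


@dataclass(frozen=True)
class TagSummary:
    """Per-deployment daylight second totals above/below the surface threshold."""

    deployment_id: str
    e_surface: float  # s, daylight time at depth < threshold
    e_dive: float     # s, daylight time at depth >= threshold
    total: float      # s, = e_surface + e_dive

    def __post_init__(self) -> None:
        if self.e_surface < 0 or self.e_dive < 0:
            raise ValidationError("tag times must be >= 0")
        if abs(self.e_surface + self.e_dive - self.total) > 0.11:
            raise ValidationError(
                f"deployment {self.deployment_id}: E_s + E_d != T "
                f"({self.e_surface} + {self.e_dive} != {self.total})"
            )
        if self.total <= 0:
            raise ValidationError(f"deployment {self.deployment_id}: empty record")

    @property
    def proportion(self) -> float:
        return self.e_surface / self.total


@dataclass
class AvailabilityEstimate:
    """Pooled surface availability with its uncertainty."""

    a_hat: float
    se: float          # sd of per-tag proportions / sqrt(n); nan for one tag
    cv: float          # between-tag dispersion / a_hat; nan for one tag
    n_tags: int
    weighting: str     # "duration" | "none"

    def __post_init__(self) -> None:
        if not 0 < self.a_hat <= 1:
            raise ValidationError("a_hat must be in (0, 1]")

    @property
    def degenerate(self) -> bool:
        """True when dispersion is undefined (a single tag)."""
        return self.n_tags < 2


def summarise_tag(
    depth_series: pd.DataFrame,
    threshold: float = 1.0,
    max_gap: float = 1.0,
) -> TagSummary:
    """Collapse one deployment's depth series to daylight surface/dive totals.

    Each retained sample represents one nominal sampling period (the median
    inter-sample interval); recording gaps longer than ``max_gap`` seconds
    are excluded from the totals rather than interpolated.  Depths are
    clamped to >= 0 first so pressure-sensor offsets cannot register as
    depth, and a sample exactly at the daylight boundary counts if its
    daylight flag is true.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    day = depth_series[depth_series["daylight"].astype(bool)]
    if len(day) == 0:
        raise ValidationError("deployment has no daylight samples")
    t = day["t"].to_numpy(dtype=float)
    depth = np.clip(day["depth"].to_numpy(dtype=float), 0.0, None)
    if len(t) > 1:
        gaps = np.diff(t)
        dt = float(np.median(gaps))
        # drop samples whose interval to the previous sample exceeds max_gap
        keep = np.concatenate([[True], gaps <= max_gap])
        depth = depth[keep]
    else:
        dt = 1.0
    n_surface = int(np.sum(depth < threshold))
    n_dive = int(np.sum(depth >= threshold))
    dep = str(day["deployment_id"].iloc[0]) if "deployment_id" in day else "tag"
    return TagSummary(
        deployment_id=dep,
        e_surface=n_surface * dt,
        e_dive=n_dive * dt,
        total=(n_surface + n_dive) * dt,
    )


def summaries_from_table(df: pd.DataFrame) -> list[TagSummary]:
    """Build :class:`TagSummary` objects from a pre-summarised table."""
    return [
        TagSummary(
            deployment_id=str(r["deployment_id"]),
            e_surface=float(r["time_above_s"]),
            e_dive=float(r["time_below_s"]),
            total=float(r["total_daylight_s"]),
        )
        for _, r in df.iterrows()
    ]


def estimate_availability(
    summaries: Sequence[TagSummary],
    weighting: str = "duration",
) -> AvailabilityEstimate:
    """Pooled surface availability over a set of tag deployments.

    With ``weighting="duration"`` (default) â = Σ E_s / Σ T, which equals
    the per-tag proportions weighted by total daylight duration; the CV is
    the duration-weighted between-tag standard deviation of the
    proportions, corrected for the effective number of tags
    (sd_w = sqrt(Σ w(p−â)² / (1 − Σ w²))), divided by â.  With
    ``weighting="none"`` â is the unweighted mean proportion and the CV its
    plain sd/mean.  The reported SE is always the unweighted sd/√n of the
    per-tag proportions.
    """
    if len(summaries) == 0:
        raise ValidationError("no tag summaries")
    if weighting not in ("duration", "none"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    p = np.array([s.proportion for s in summaries])
    T = np.array([s.total for s in summaries])
    n = len(summaries)

    if weighting == "duration":
        a_hat = float(np.sum([s.e_surface for s in summaries]) / T.sum())
        w = T / T.sum()
        if n > 1:
            sd_w = float(np.sqrt(np.sum(w * (p - a_hat) ** 2) / (1.0 - np.sum(w**2))))
            cv = sd_w / a_hat
        else:
            cv = float("nan")
    else:
        a_hat = float(p.mean())
        cv = float(p.std(ddof=1) / a_hat) if n > 1 else float("nan")

    se = float(p.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return AvailabilityEstimate(a_hat=a_hat, se=se, cv=cv, n_tags=n, weighting=weighting)


def adjust_density(
    d_hat: DensityEstimate, a: AvailabilityEstimate
) -> DensityEstimate:
    """Correct a snapshot density for availability bias: d̂/â.

    The adjusted CV combines the input CV with the availability CV in
    quadrature (first-order delta method for a ratio of independent
    estimates).
    """
    if a.a_hat <= 0:
        raise ValidationError("availability must be > 0")
    cv_a = 0.0 if np.isnan(a.cv) else a.cv
    components = dict(d_hat.components)
    components["availability"] = cv_a
    return replace(
        d_hat,
        density=d_hat.density / a.a_hat,
        cv=float(np.sqrt(d_hat.cv**2 + cv_a**2)),
        adjusted=True,
        components=components,
    )
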