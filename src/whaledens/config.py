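"""Survey-geometry configuration.

Units are fixed package-wide: distances km, depths m, times s, areas km²,
densities whales/km².
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from whaledens.errors import SchemaError, ValidationError

#: Default weights for the 13 FOI criteria: the four highly indicative
#: criteria (fluke, fins, footprint, blow) carry weight 2, the rest weight 1.
DEFAULT_CRITERION_WEIGHTS: tuple[int, ...] = (2, 2, 2, 2, 1, 1, 1, 1, 1, 1, 1, 1, 1)


@dataclass
class SurveyConfig:
    """Geometry and thresholds of an image-plus-ship survey.

    Parameters
    ----------
    image_area_total:
        Total scanned image area in km², counting overlap regions once per
        image (the denominator of satellite densities).
    area_calmer, area_rougher:
        Areas of the calmer / rougher sea-state strata; they must sum to
        ``image_area_total``.
    surface_threshold:
        Depth in metres above which a whale counts as available to an
        overhead platform (strictly shallower than the threshold).
    esw_override:
        Effective half strip width in km to use instead of a fitted one,
        e.g. when only summary statistics of the ship survey are available.
    truncation_distance:
        Right-truncation distance in km for detection-function fitting,
        or ``None`` for no truncation.
    criterion_weights:
        Weight applied to each of the 13 FOI criteria when forming the
        total score.
    """

    image_area_total: float
    area_calmer: float
    area_rougher: float
    surface_threshold: float = 1.0
    esw_override: float | None = None
    truncation_distance: float | None = None
    criterion_weights: tuple[int, ...] = field(default=DEFAULT_CRITERION_WEIGHTS)

    def __post_init__(self) -> None:
        for name in ("image_area_total", "area_calmer", "area_rougher"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if abs(self.area_calmer + self.area_rougher - self.image_area_total) > 1e-6:
            raise ValidationError(
                "area_calmer + area_rougher must equal image_area_total "
                f"({self.area_calmer} + {self.area_rougher} != {self.image_area_total})"
            )
        if self.surface_threshold <= 0:
            raise ValidationError("surface_threshold must be > 0")
        self.criterion_weights = tuple(self.criterion_weights)
        if len(self.criterion_weights) != 13:
            raise ValidationError("criterion_weights must have exactly 13 entries")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SurveyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise SchemaError(f"config file {path} is not a mapping")
        required = {"image_area_total", "area_calmer", "area_rougher"}
        missing = required - raw.keys()
        if missing:
            raise SchemaError(f"config missing required keys: {sorted(missing)}")
        known = {
            "image_area_total",
            "area_calmer",
            "area_rougher",
            "surface_threshold",
            "esw_override",
            "truncation_distance",
            "criterion_weights",
        }
        unknown = raw.keys() - known
        if unknown:
            raise SchemaError(f"config has unknown keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["criterion_weights"] = list(self.criterion_weights)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
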