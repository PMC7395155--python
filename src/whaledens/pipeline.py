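"""Pipeline orchestration: simulate/load → fit → score → adjust → report.

Three modes are supported:

* ``reference`` — run the analysis on the bundled printed-input dataset
  (tag summary rows, FOI class counts, areas, ship summary statistics);
* ``files`` — run on user CSVs (sightings, effort, FOI table, tag depths
  or tag summaries) plus a survey config;
* ``simulate`` — generate all inputs synthetically at a known truth, then
  analyse them.

Every run writes a manifest recording the tool version, config hash, input
digests, seed and the ordered stage list; result files are pure functions
of the inputs so identical configs reproduce identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

import whaledens
from whaledens import datasets, io_formats
from whaledens.availability import (
    estimate_availability,
    summaries_from_table,
    summarise_tag,
)
from whaledens.config import SurveyConfig
from whaledens.density_report import build_comparison, satellite_density
from whaledens.distance_sampling import (
    HALF_NORMAL,
    HAZARD_RATE,
    cvm_test,
    fit_detection,
    mean_group_size,
    select_model,
    ship_density,
)
from whaledens.errors import ValidationError
from whaledens.foi_scoring import count_classes, stratify_counts
from whaledens.synthetic import (
    SimulationScenario,
    simulate_dive_profiles,
    simulate_foi_table,
    simulate_population,
    simulate_ship_survey,
)

logger = logging.getLogger(__name__)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict, out_dir: str | Path, seed: int = 0) -> dict:
    """Run the configured analysis end to end; returns the manifest.

    Outputs written to ``out_dir``: ``table2.csv`` (per-class raw and
    availability-adjusted densities), ``ratios.txt``, ``estimates.json``
    (all estimates with CV components), ``model_table.csv`` when detection
    functions are fitted, and ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mode = config.get("mode", "reference")
    stages: list[str] = []
    input_digests: dict[str, str] = {}

    # pre-flight: every referenced input must exist before compute starts
    if mode == "files":
        inputs = config.get("inputs", {})
        required = ["sightings", "effort", "foi"]
        if "tag_depths" not in inputs and "tag_summaries" not in inputs:
            raise ValidationError("config must name tag_depths or tag_summaries")
        missing = [k for k in required if k not in inputs]
        if missing:
            raise ValidationError(f"config missing input path(s): {missing}")
        for key, p in inputs.items():
            if not Path(p).exists():
                raise ValidationError(f"input file for {key!r} not found: {p}")
            input_digests[key] = _digest(Path(p))

    rng = np.random.default_rng(seed)
    estimates: dict[str, dict] = {}

    if mode == "reference":
        cfg = datasets.survey_config()
        ship_sum = datasets.ship_summary()
        counts = datasets.foi_counts()
        tag_table = datasets.tag_summaries()
        stages.append("load-reference")
        logger.info("reference dataset: areas %s/%s km², threshold %s m",
                    cfg.area_calmer, cfg.area_rougher, cfg.surface_threshold)

        stages.append("availability")
        avail = estimate_availability(summaries_from_table(tag_table), "duration")

        stages.append("ship-density")
        ship = ship_density(
            ship_sum["n_groups"], ship_sum["mean_group_size"],
            ship_sum["esw"], ship_sum["effort_L"],
            {
                "encounter_rate": ship_sum["cv_encounter_rate"],
                "detection": ship_sum["cv_esw"],
                "group_size": ship_sum["cv_group_size"],
            },
        )

        stages.append("satellite-density")
        sats = [
            satellite_density(counts, cfg.image_area_total, sel)
            for sel in ("definite", "probable", "unclassified", "definite+probable")
        ]

    elif mode in ("files", "simulate"):
        if mode == "simulate":
            stages.append("simulate")
            scenario = SimulationScenario(
                **{**config.get("scenario", {}), "seed": seed}
            )
            cfg = SurveyConfig(
                image_area_total=scenario.area_total,
                area_calmer=scenario.area_calmer,
                area_rougher=scenario.area_rougher,
            )
            pop = simulate_population(scenario, rng)
            sightings, effort = simulate_ship_survey(scenario, pop, rng)
            foi_df, truth = simulate_foi_table(scenario, pop, rng)
            profiles = simulate_dive_profiles(
                scenario, n_tags=config.get("n_tags", 8),
                duration_s=config.get("tag_duration_s", 4 * 3600.0), rng=rng,
            )
            io_formats.write_sightings(sightings, out / "sightings.csv")
            io_formats.write_effort(effort, out / "effort.csv")
            foi_df.to_csv(out / "foi.csv", index=False)
            truth.to_csv(out / "truth.csv", index=False)
            records = io_formats.read_foi_table(out / "foi.csv", cfg.criterion_weights)
            tags = [
                summarise_tag(series, cfg.surface_threshold)
                for series in profiles.values()
            ]
            truncation = scenario.truncation_w
        else:
            stages.append("load-files")
            inputs = config["inputs"]
            cfg = SurveyConfig(**config["survey"])
            sightings = io_formats.read_sightings(inputs["sightings"])
            effort = io_formats.read_effort(inputs["effort"])
            records = io_formats.read_foi_table(inputs["foi"], cfg.criterion_weights)
            if "tag_summaries" in inputs:
                tags = summaries_from_table(
                    io_formats.read_tag_summaries(inputs["tag_summaries"])
                )
            else:
                profiles = io_formats.read_tag_depths(inputs["tag_depths"])
                tags = [
                    summarise_tag(series, cfg.surface_threshold)
                    for series in profiles.values()
                ]
            truncation = cfg.truncation_distance

        stages.append("ship-fit")
        fits = []
        for key in (HALF_NORMAL, HAZARD_RATE):
            try:
                f = fit_detection(
                    sightings["perp_distance"], key=key, truncation_w=truncation
                )
                f.cvm_p = cvm_test(f, sightings["perp_distance"])[1]
                fits.append(f)
            except Exception as exc:  # a failed candidate is reported, not fatal
                logger.warning("%s fit failed: %s", key, exc)
        best, model_table = select_model(fits)
        model_table.to_csv(out / "model_table.csv", index=False)

        stages.append("ship-density")
        ms, cv_ms = mean_group_size(sightings["group_size"])
        ship = ship_density(
            len(sightings), ms, best.esw, effort["length"].sum(),
            {"detection": best.se_p_a / best.p_a, "group_size": cv_ms},
        )

        stages.append("foi-score")
        counts = count_classes(records)
        strata = stratify_counts(records)

        stages.append("availability")
        avail = estimate_availability(tags, "duration")

        stages.append("satellite-density")
        sats = [
            satellite_density(counts, cfg.image_area_total, sel)
            for sel in ("definite", "probable", "unclassified", "definite+probable")
        ]
        estimates["strata"] = {
            k: {
                "n_definite": v["counts"].n_definite,
                "n_probable": v["counts"].n_probable,
                "n_unclassified": v["counts"].n_unclassified,
                "p_definite_probable": v.get("p_definite_probable"),
                "se": v.get("se"),
            }
            for k, v in strata.items()
        }
    else:
        raise ValidationError(f"unknown pipeline mode {mode!r}")

    stages.append("adjust-and-report")
    report = build_comparison(ship, sats, avail)
    report.to_csv(out / "table2.csv")
    (out / "ratios.txt").write_text(report.ratios_text())

    estimates.update(
        {
            "ship": {"density": ship.density, "cv": ship.cv, "components": ship.components},
            "availability": {
                "a_hat": avail.a_hat, "se": avail.se,
                "cv": avail.cv, "n_tags": avail.n_tags,
            },
            "satellite": [
                {
                    "class": s.foi_class, "stratum": s.stratum,
                    "density": s.density, "cv": s.cv,
                    "density_adjusted": s.density / avail.a_hat,
                    "cv_adjusted": float(np.sqrt(s.cv**2 + avail.cv**2)),
                }
                for s in sats
            ],
            "ratios": {k: v for k, v in report.ratios.items() if np.isfinite(v)},
        }
    )
    (out / "estimates.json").write_text(json.dumps(estimates, indent=2))

    manifest = {
        "tool": "whaledens",
        "version": whaledens.__version__,
        "config_hash": _config_hash(config),
        "input_digests": input_digests,
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "stages": stages,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
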