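"""Synthetic whale-survey generator with known ground truth.

Emulates the three input families the analysis pipeline consumes:

* a whale population as a homogeneous Poisson point process over a
  rectangular region at a known density, with zero-truncated-Poisson group
  sizes;
* archival-tag dive profiles as an alternating renewal process of surface
  and dive bouts (exponential durations by default), emitted as a
  10 Hz depth series with a daylight mask — the long-run surface fraction
  is surface_mean / (surface_mean + dive_mean);
* a ship line-transect survey that thins in-strip groups by the detection
  function g(perpendicular distance), and a satellite snapshot in which
  whales at the surface at the acquisition instant emit 13-criterion score
  vectors, degraded by sea state, alongside clutter features from a noise
  emission table.

Every generator takes a :class:`numpy.random.Generator` derived from the
scenario seed, so a fixed seed reproduces outputs exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize

from whaledens.distance_sampling import HALF_NORMAL, HAZARD_RATE, _g
from whaledens.errors import ValidationError
from whaledens.foi_scoring import SEA_STATE_STRATUM

#: Whale criterion-emission table in calm water: P(score = 0, 1, 2) for the
#: four weighted criteria (fluke, fins, footprint, blow) and the nine
#: unweighted ones.  Tuned so that, under the reference scenario, the
#: definite : probable : unclassified proportions of the generated FOI table
#: are close to the 18 : 21 : 146 split of the bundled reference survey.
WHALE_EMISSION_WEIGHTED = (0.48, 0.42, 0.10)
WHALE_EMISSION_UNWEIGHTED = (0.40, 0.52, 0.08)

#: Clutter (noise) emission: unusual surface disturbances score low.
NOISE_EMISSION = (0.86, 0.11, 0.03)

#: Probability that a criterion score is downgraded one step, per sea state.
DEFAULT_DEGRADATION: Mapping[str, float] = {
    "ideal": 0.0,
    "good": 0.05,
    "average": 0.12,
    "sub-average": 0.35,
    "poor": 0.50,
}


@dataclass
class SimulationScenario:
    """Ground-truth configuration of one simulated survey.

    Defaults mirror the reference survey conditions: whale density 0.33
    whales/km² (the ship estimate), mean group size 2.06, a 971 km² image
    region split 635/336 km² into calmer/rougher strata, surface/dive bout
    means giving a long-run surface fraction of 0.34, and a half-normal
    ship detection function with σ = 1.5 km truncated at 6 km.
    """

    true_density: float = 0.33          # whales / km²
    region_width: float = 12.0          # km, across-track extent
    area_calmer: float = 635.0          # km²
    area_rougher: float = 336.0         # km²
    mean_group_size: float = 2.06
    surface_bout_mean: float = 60.0     # s
    dive_bout_mean: float = 117.0       # s  -> surface fraction 60/177 ≈ 0.339
    detection_key: str = HALF_NORMAL
    detection_sigma: float = 1.5        # km
    detection_shape: float = 2.5        # hazard-rate only
    truncation_w: float = 6.0           # km
    sample_hz: float = 10.0
    noise_foi_rate: float = 0.42        # clutter FOIs per km²
    whale_emission_weighted: tuple[float, float, float] = WHALE_EMISSION_WEIGHTED
    whale_emission_unweighted: tuple[float, float, float] = WHALE_EMISSION_UNWEIGHTED
    noise_emission: tuple[float, float, float] = NOISE_EMISSION
    degradation: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DEGRADATION))
    seed: int = 0

    @property
    def area_total(self) -> float:
        return self.area_calmer + self.area_rougher

    @property
    def region_height(self) -> float:
        return self.area_total / self.region_width

    @property
    def calmer_height(self) -> float:
        """Calmer stratum occupies y < calmer_height (the sheltered north)."""
        return self.area_calmer / self.region_width

    @property
    def surface_fraction(self) -> float:
        """Long-run fraction of time above the surface threshold."""
        if self.dive_bout_mean <= 0:
            return 1.0
        return self.surface_bout_mean / (self.surface_bout_mean + self.dive_bout_mean)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _ztp_lambda(mean: float) -> float:
    """Rate of a zero-truncated Poisson with the given mean."""
    if mean <= 1.0:
        raise ValidationError("zero-truncated Poisson mean must be > 1")
    f = lambda lam: lam / (1.0 - np.exp(-lam)) - mean
    return float(optimize.brentq(f, 1e-9, 10.0 * mean))


def _sample_ztp(rng: np.random.Generator, lam: float, n: int) -> np.ndarray:
    """Zero-truncated Poisson sampling by inverse CDF on the shifted pmf."""
    if n == 0:
        return np.zeros(0, dtype=int)
    out = rng.poisson(lam, size=n)
    while True:
        zero = out == 0
        if not zero.any():
            return out
        out[zero] = rng.poisson(lam, size=int(zero.sum()))


def simulate_population(
    scenario: SimulationScenario, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Whale groups as a homogeneous Poisson point process at the true density.

    Returns a frame with columns x, y (km) and group_size; the expected
    total of individuals is true_density × area.
    """
    rng = rng if rng is not None else scenario.rng()
    group_density = scenario.true_density / scenario.mean_group_size
    n_groups = rng.poisson(group_density * scenario.area_total)
    if n_groups == 0:
        return pd.DataFrame(columns=["x", "y", "group_size"]).astype(
            {"x": float, "y": float, "group_size": int}
        )
    lam = _ztp_lambda(scenario.mean_group_size)
    return pd.DataFrame(
        {
            "x": rng.uniform(0.0, scenario.region_width, n_groups),
            "y": rng.uniform(0.0, scenario.region_height, n_groups),
            "group_size": _sample_ztp(rng, lam, n_groups),
        }
    )


def simulate_dive_profiles(
    scenario: SimulationScenario,
    n_tags: int,
    duration_s: float,
    rng: np.random.Generator | None = None,
) -> dict[str, pd.DataFrame]:
    """Alternating surface/dive bouts emitted as depth series with daylight mask.

    Bout durations are exponential with the scenario means; surface samples
    sit between 0 and 0.8 m, dive samples between 5 and 40 m.  The initial
    state is drawn from the stationary distribution of the renewal process.
    """
    rng = rng if rng is not None else scenario.rng()
    if duration_s <= 0 or n_tags <= 0:
        raise ValidationError("need positive n_tags and duration")
    dt = 1.0 / scenario.sample_hz
    out: dict[str, pd.DataFrame] = {}
    for tag in range(n_tags):
        dep = f"sim-{tag:03d}"
        n_samples = int(round(duration_s * scenario.sample_hz))
        if scenario.dive_bout_mean <= 0:
            depth = rng.uniform(0.0, 0.8, n_samples)
        else:
            states, counts = [], []
            t_acc = 0.0
            state = rng.random() < scenario.surface_fraction  # True = surface
            while t_acc < duration_s:
                mean = scenario.surface_bout_mean if state else scenario.dive_bout_mean
                bout = rng.exponential(mean)
                k = int(round(min(bout, duration_s - t_acc) * scenario.sample_hz))
                if k > 0:
                    states.append(state)
                    counts.append(k)
                t_acc += bout
                state = not state
            counts = np.asarray(counts)
            surface_mask = np.repeat(np.asarray(states, bool), counts)
            n_samples = len(surface_mask)
            depth = np.where(
                surface_mask,
                rng.uniform(0.0, 0.8, n_samples),
                rng.uniform(5.0, 40.0, n_samples),
            )
        out[dep] = pd.DataFrame(
            {
                "deployment_id": dep,
                "t": np.arange(n_samples) * dt,
                "depth": depth,
                "daylight": True,
            }
        )
    return out


def simulate_ship_survey(
    scenario: SimulationScenario,
    population: pd.DataFrame,
    rng: np.random.Generator | None = None,
    transect_x: tuple[float, ...] | None = None,
    availability: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Thin in-strip groups by the detection function along parallel transects.

    Each transect runs the full region height at the given across-track
    position (default: the region mid-line).  A group at perpendicular
    distance d from the nearest transect is detected with probability
    g(d) × availability for d ≤ truncation_w.  Detection is certain on the
    trackline (g(0) = 1); sighting covariates are drawn independently of
    detection, so the default generator has no true covariate effect.
    """
    rng = rng if rng is not None else scenario.rng()
    tx = np.asarray(transect_x if transect_x is not None else [scenario.region_width / 2.0])
    sightings = []
    if len(population) > 0:
        x = population["x"].to_numpy()
        d = np.min(np.abs(x[:, None] - tx[None, :]), axis=1)
        in_strip = d <= scenario.truncation_w
        g = _g(
            scenario.detection_key,
            d,
            np.full_like(d, scenario.detection_sigma),
            scenario.detection_shape if scenario.detection_key == HAZARD_RATE else None,
        )
        detected = in_strip & (rng.random(len(d)) < g * availability)
        for i in np.flatnonzero(detected):
            sightings.append(
                {
                    "perp_distance": d[i],
                    "group_size": int(population["group_size"].iloc[i]),
                    "species": "humpback",
                    "beaufort": int(rng.integers(0, 5)),
                    "visibility": rng.choice(["Good", "Fair", "Poor"], p=[0.6, 0.3, 0.1]),
                    "sightability": int(rng.integers(0, 4)),
                }
            )
    sightings_df = pd.DataFrame(
        sightings,
        columns=["perp_distance", "group_size", "species", "beaufort", "visibility", "sightability"],
    )
    effort_df = pd.DataFrame(
        {
            "transect_id": [f"T{i + 1}" for i in range(len(tx))],
            "length": np.full(len(tx), scenario.region_height),
        }
    )
    return sightings_df, effort_df


def _emit_scores(
    rng: np.random.Generator,
    n: int,
    weighted_probs: tuple[float, float, float],
    unweighted_probs: tuple[float, float, float],
    degradation: np.ndarray,
) -> np.ndarray:
    """Draw n × 13 criterion scores and apply per-FOI degradation."""
    scores = np.empty((n, 13), dtype=int)
    scores[:, :4] = rng.choice(3, size=(n, 4), p=weighted_probs)
    scores[:, 4:] = rng.choice(3, size=(n, 9), p=unweighted_probs)
    downgrade = rng.random((n, 13)) < degradation[:, None]
    return np.maximum(scores - downgrade.astype(int), 0)


def simulate_foi_table(
    scenario: SimulationScenario,
    population: pd.DataFrame,
    rng: np.random.Generator | None = None,
    perfect: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Satellite snapshot: surface whales and clutter emit criterion vectors.

    Each individual whale is independently at the surface at the snapshot
    instant with the scenario's long-run surface fraction.  Surfaced whales
    emit scores from the whale emission tables (degraded by the sea state of
    their stratum); clutter FOIs arrive as a Poisson process at the noise
    rate and emit from the noise table.  With ``perfect=True`` whales score
    2 on every criterion and no clutter is generated (ideal classification).

    Returns the FOI table in the standard schema plus a ground-truth frame
    (foi_id, is_whale).
    """
    rng = rng if rng is not None else scenario.rng()
    calm_states = [s for s, st in SEA_STATE_STRATUM.items() if st == "calmer"]
    rough_states = [s for s, st in SEA_STATE_STRATUM.items() if st == "rougher"]

    # expand groups to individuals and thin by instantaneous availability
    if len(population) > 0:
        sizes = population["group_size"].to_numpy(dtype=int)
        ys = np.repeat(population["y"].to_numpy(), sizes)
        surfaced = rng.random(len(ys)) < scenario.surface_fraction
        whale_y = ys[surfaced]
    else:
        whale_y = np.zeros(0)

    rows = []
    truth = []

    def _add(y: float, is_whale: bool, idx: int) -> None:
        stratum = "calmer" if y < scenario.calmer_height else "rougher"
        sea_state = rng.choice(calm_states if stratum == "calmer" else rough_states)
        rows.append((f"{'W' if is_whale else 'N'}{idx:05d}", sea_state, stratum))
        truth.append(is_whale)

    for i, y in enumerate(whale_y):
        _add(float(y), True, i)
    n_whales = len(whale_y)

    if not perfect and scenario.noise_foi_rate > 0:
        n_noise = rng.poisson(scenario.noise_foi_rate * scenario.area_total)
        noise_y = rng.uniform(0.0, scenario.region_height, n_noise)
        for i, y in enumerate(noise_y):
            _add(float(y), False, i)
    else:
        n_noise = 0

    if not rows:
        empty = pd.DataFrame(
            columns=["foi_id", *[f"psi{i}" for i in range(1, 14)], "sea_state", "stratum", "observer"]
        )
        return empty, pd.DataFrame(columns=["foi_id", "is_whale"])

    degr = np.array([scenario.degradation[s] for _, s, _ in rows])
    if perfect:
        scores = np.full((len(rows), 13), 2, dtype=int)
    else:
        scores = np.empty((len(rows), 13), dtype=int)
        if n_whales:
            scores[:n_whales] = _emit_scores(
                rng, n_whales,
                scenario.whale_emission_weighted,
                scenario.whale_emission_unweighted,
                degr[:n_whales],
            )
        if n_noise:
            scores[n_whales:] = _emit_scores(
                rng, n_noise, scenario.noise_emission, scenario.noise_emission,
                degr[n_whales:],
            )

    table = pd.DataFrame(
        {
            "foi_id": [r[0] for r in rows],
            **{f"psi{i + 1}": scores[:, i] for i in range(13)},
            "sea_state": [r[1] for r in rows],
            "stratum": [r[2] for r in rows],
            "observer": "O1",
        }
    )
    truth_df = pd.DataFrame({"foi_id": [r[0] for r in rows], "is_whale": truth})
    return table, truth_df
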