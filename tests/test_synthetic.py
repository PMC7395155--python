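import numpy as np
import pandas as pd
import pytest
from scipy import stats

from whaledens.availability import estimate_availability, summarise_tag
from whaledens.distance_sampling import fit_detection, mean_group_size, ship_density
from whaledens.foi_scoring import classify, score_foi
from whaledens.synthetic import (
    SimulationScenario,
    simulate_dive_profiles,
    simulate_foi_table,
    simulate_population,
    simulate_ship_survey,
)


class TestPopulation:
    def test_poisson_mean_count(self):
        # density 0.33 over 971 km²: expected whales ≈ 320
        totals = []
        for i in range(300):
            scenario = SimulationScenario(seed=i, true_density=0.33)
            pop = simulate_population(scenario)
            totals.append(pop["group_size"].sum())
        expected = 0.33 * 971.0
        se = np.std(totals) / np.sqrt(len(totals))
        assert abs(np.mean(totals) - expected) < 3 * se

    def test_group_size_mean_matches_config(self):
        scenario = SimulationScenario(seed=5, true_density=4.0)
        pop = simulate_population(scenario)
        assert pop["group_size"].mean() == pytest.approx(2.06, abs=0.05)
        assert (pop["group_size"] >= 1).all()

    def test_zero_density_empty(self):
        pop = simulate_population(SimulationScenario(seed=1, true_density=0.0))
        assert len(pop) == 0

    def test_seed_determinism(self):
        a = simulate_population(SimulationScenario(seed=9))
        b = simulate_population(SimulationScenario(seed=9))
        pd.testing.assert_frame_equal(a, b)


class TestDiveProfiles:
    def test_long_run_surface_fraction(self):
        scenario = SimulationScenario(seed=2, sample_hz=1.0)
        profiles = simulate_dive_profiles(scenario, n_tags=1, duration_s=20 * 3600.0)
        (df,) = profiles.values()
        frac = float(np.mean(df["depth"] < 1.0))
        assert frac == pytest.approx(60.0 / 177.0, abs=0.02)

    def test_no_diving_always_available(self):
        scenario = SimulationScenario(seed=3, dive_bout_mean=0.0, sample_hz=1.0)
        profiles = simulate_dive_profiles(scenario, n_tags=1, duration_s=3600.0)
        (df,) = profiles.values()
        assert (df["depth"] < 1.0).all()

    def test_seed_determinism(self):
        s = SimulationScenario(seed=4, sample_hz=1.0)
        a = simulate_dive_profiles(s, 2, 600.0)
        b = simulate_dive_profiles(SimulationScenario(seed=4, sample_hz=1.0), 2, 600.0)
        for k in a:
            pd.testing.assert_frame_equal(a[k], b[k])

    def test_profiles_feed_availability_estimator(self):
        scenario = SimulationScenario(seed=6, sample_hz=1.0)
        profiles = simulate_dive_profiles(scenario, n_tags=6, duration_s=6 * 3600.0)
        tags = [summarise_tag(p, 1.0) for p in profiles.values()]
        est = estimate_availability(tags, "duration")
        assert est.a_hat == pytest.approx(scenario.surface_fraction, abs=0.05)


class TestShipSurvey:
    def test_perfect_detection_counts_everything_in_strip(self):
        scenario = SimulationScenario(
            seed=8, detection_sigma=1e6, true_density=1.0
        )  # σ → ∞ makes g ≈ 1 everywhere
        pop = simulate_population(scenario)
        sightings, _ = simulate_ship_survey(scenario, pop)
        d = np.abs(pop["x"] - scenario.region_width / 2.0)
        assert len(sightings) == int((d <= scenario.truncation_w).sum())

    def test_detected_distances_follow_detection_function(self):
        # χ² GOF of detected perpendicular distances against the expected
        # truncated half-normal shape
        scenario = SimulationScenario(seed=10, true_density=20.0, region_width=12.0)
        pop = simulate_population(scenario)
        sightings, _ = simulate_ship_survey(scenario, pop)
        assert len(sightings) > 2000
        d = sightings["perp_distance"].to_numpy()
        edges = np.linspace(0, scenario.truncation_w, 13)
        observed, _ = np.histogram(d, bins=edges)
        sig = scenario.detection_sigma
        cdf = stats.norm.cdf(edges, scale=sig) - 0.5  # ∝ ∫ g over [0, edge]
        mass = np.diff(cdf)
        expected = mass / mass.sum() * observed.sum()
        chi2 = ((observed - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, len(observed) - 1)
        assert p > 0.01

    def test_effort_matches_region_height(self):
        scenario = SimulationScenario(seed=11)
        pop = simulate_population(scenario)
        _, effort = simulate_ship_survey(scenario, pop)
        assert effort["length"].sum() == pytest.approx(scenario.region_height)

    def test_full_pipeline_density_recovery(self):
        # simulate → fit → estimate: the mean recovered density over
        # replicates is within 5% of the simulated truth
        estimates = []
        for i in range(150):
            scenario = SimulationScenario(seed=20_000 + i, true_density=0.33)
            rng = scenario.rng()
            pop = simulate_population(scenario, rng)
            sightings, effort = simulate_ship_survey(scenario, pop, rng)
            if len(sightings) < 20:
                continue
            fit = fit_detection(
                sightings["perp_distance"], key="half-normal",
                truncation_w=scenario.truncation_w,
            )
            ms, _ = mean_group_size(sightings["group_size"])
            est = ship_density(len(sightings), ms, fit.esw, effort["length"].sum())
            estimates.append(est.density)
        assert len(estimates) > 140
        assert np.mean(estimates) == pytest.approx(0.33, rel=0.05)


class TestFOITable:
    def test_perfect_classification_counts_available_whales(self):
        scenario = SimulationScenario(seed=30, true_density=1.0)
        rng = scenario.rng()
        pop = simulate_population(scenario, rng)
        foi, truth = simulate_foi_table(scenario, pop, rng, perfect=True)
        assert truth["is_whale"].all()
        scores = foi[[f"psi{i}" for i in range(1, 14)]].to_numpy()
        labels = [classify(score_foi(row)) for row in scores]
        assert set(labels) == {"definite"}
        # the count is the snapshot-available subset of the population
        assert len(foi) <= pop["group_size"].sum()

    def test_thinning_identity(self):
        # E[definite∪probable] ≈ availability × density × area under
        # perfect classification
        counts = []
        for i in range(200):
            scenario = SimulationScenario(seed=40_000 + i, true_density=0.33)
            rng = scenario.rng()
            pop = simulate_population(scenario, rng)
            foi, _ = simulate_foi_table(scenario, pop, rng, perfect=True)
            counts.append(len(foi))
        expected = (60.0 / 177.0) * 0.33 * 971.0
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_rough_stratum_degrades_classification(self):
        # sign test: the rougher stratum's definite∪probable proportion is
        # below the calmer one in a clear majority of replicates
        wins = trials = 0
        for i in range(100):
            scenario = SimulationScenario(seed=50_000 + i, true_density=1.0)
            rng = scenario.rng()
            pop = simulate_population(scenario, rng)
            foi, truth = simulate_foi_table(scenario, pop, rng)
            whale_ids = set(truth.loc[truth["is_whale"], "foi_id"])
            whales = foi[foi["foi_id"].isin(whale_ids)]
            scores = whales[[f"psi{i}" for i in range(1, 14)]].to_numpy()
            labels = np.array([classify(score_foi(r)) for r in scores])
            good = np.isin(labels, ["definite", "probable"])
            props = {}
            for stratum in ("calmer", "rougher"):
                mask = (whales["stratum"] == stratum).to_numpy()
                if mask.sum() >= 10:
                    props[stratum] = good[mask].mean()
            if len(props) == 2:
                trials += 1
                wins += props["rougher"] < props["calmer"]
        assert trials > 80
        assert stats.binomtest(wins, trials, 0.5, alternative="greater").pvalue < 1e-6

    def test_outputs_pass_schema_validation(self, tmp_path):
        from whaledens import io_formats

        scenario = SimulationScenario(seed=31)
        rng = scenario.rng()
        pop = simulate_population(scenario, rng)
        foi, _ = simulate_foi_table(scenario, pop, rng)
        path = tmp_path / "foi.csv"
        foi.to_csv(path, index=False)
        records = io_formats.read_foi_table(path)
        assert len(records) == len(foi)

    def test_seed_determinism(self):
        def run():
            scenario = SimulationScenario(seed=32)
            rng = scenario.rng()
            pop = simulate_population(scenario, rng)
            return simulate_foi_table(scenario, pop, rng)[0]

        pd.testing.assert_frame_equal(run(), run())


class TestEndToEndSatellite:
    def test_adjusted_density_recovers_truth(self):
        # the pipeline's core logic: snapshot counts divided by the known
        # availability recover the true density on average
        true_density = 0.33
        adjusted = []
        for i in range(200):
            scenario = SimulationScenario(seed=60_000 + i, true_density=true_density)
            rng = scenario.rng()
            pop = simulate_population(scenario, rng)
            foi, _ = simulate_foi_table(scenario, pop, rng, perfect=True)
            adjusted.append(len(foi) / scenario.area_total / scenario.surface_fraction)
        assert np.mean(adjusted) == pytest.approx(true_density, rel=0.05)
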