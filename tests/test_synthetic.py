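"""The synthetic world: determinism, coverage, self-consistency, trends."""

import dataclasses

import numpy as np
import pytest

from dietcra.io import sha256_of
from dietcra.paf import compute_paf
from dietcra.risk_model import (
    Direction,
    ExposureDistribution,
    RelativeRiskCurve,
    RiskFactor,
    ValidationError,
)
from dietcra.synthetic import (
    SyntheticRisk,
    WorldBundle,
    WorldSpec,
    calibrate_attributable_deaths,
    default_risks,
    generate_two_period_world,
    generate_world,
)


class TestGeneration:
    def test_same_seed_byte_identical_bundle(self, tmp_path, default_bundle):
        again = generate_world(WorldSpec(seed=7))
        d1, d2 = tmp_path / "a", tmp_path / "b"
        default_bundle.write(d1)
        again.write(d2)
        for f in sorted(p.name for p in d1.iterdir()):
            assert sha256_of(d1 / f) == sha256_of(d2 / f), f

    def test_bundle_round_trips_through_directory(self, tmp_path, default_bundle):
        default_bundle.write(tmp_path / "w")
        back = WorldBundle.read(tmp_path / "w")
        assert np.allclose(
            back.ground_truth_paf["paf_true"],
            default_bundle.ground_truth_paf["paf_true"],
        )
        assert back.config["risks"].keys() == default_bundle.config["risks"].keys()

    def test_sparse_coverage_leaves_most_countries_without_data(self):
        spec = WorldSpec(seed=3)
        bundle = generate_world(spec)
        countries = bundle.hierarchy_tree().countries()
        covered = set(
            bundle.surveys.loc[bundle.surveys["risk"] == "red meat", "location"]
        )
        # red meat coverage 0.17: at least 80% of countries have no data
        assert len(covered) <= 0.2 * len(countries) + 1
        assert len(covered) == round(0.17 * len(countries))

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValidationError):
            WorldSpec(n_countries_per=0)

    def test_survey_se_positive_even_noise_free(self):
        spec = WorldSpec(seed=5, survey_noise_scale=0.0)
        bundle = generate_world(spec)
        assert (bundle.surveys["se"] > 0).all()


class TestGroundTruthSelfConsistency:
    def test_truth_pafs_recomputable_from_true_parameters(self, default_bundle):
        """The bundle's stated PAFs follow from its own true-parameter tables."""
        truth = default_bundle.ground_truth_paf.sample(20, random_state=0)
        exp = default_bundle.ground_truth_exposure.set_index(
            ["risk", "location", "year", "sex", "age_lower", "age_upper"]
        )
        rr = default_bundle.relative_risks.set_index(["risk", "outcome"])
        tmrel = default_bundle.tmrels.set_index("risk")["optimal"]
        cfg = default_bundle.config["risks"]
        for row in truth.to_dict("records"):
            key = (row["risk"], row["location"], row["year"], row["sex"],
                   row["age_lower"], row["age_upper"])
            true_mean = exp.loc[key, "true_mean"]
            true_sd = exp.loc[key, "true_sd"]
            lrr = rr.loc[(row["risk"], row["outcome"]), "log_rr_per_unit"]
            rf = RiskFactor(row["risk"], Direction(cfg[row["risk"]]["direction"]))
            curve = RelativeRiskCurve(rf, row["outcome"], float(lrr))
            dist = ExposureDistribution(float(true_mean), float(true_sd))
            paf = compute_paf(dist, curve, float(tmrel[row["risk"]]))
            assert paf == pytest.approx(row["paf_true"], abs=1e-8)

    def test_estimation_error_shrinks_with_survey_sample_size(self):
        from dietcra.pipeline import estimate_all_exposures

        risk = dataclasses.replace(
            default_risks()[0],
            coverage=1.0,
            log_rr={"ischemic_heart_disease": (np.log(1.30) / 300.0, 2.0e-4)},
        )
        base = WorldSpec(
            n_super_regions=1, n_regions_per=1, n_countries_per=3,
            age_groups=((35, 55), (55, 75)), sexes=("female",), years=(2013,),
            risks=(risk,), yll_per_death=(30.0, 15.0),
            outcome_baseline_rates=(("ischemic_heart_disease", 50.0),),
        )
        rmse = {}
        for n in (50, 1000):
            errs = []
            for rep in range(10):
                spec = dataclasses.replace(base, survey_sample_size=n, seed=200 + rep)
                bundle = generate_world(spec)
                est = estimate_all_exposures(bundle)
                m = est.merge(
                    bundle.ground_truth_exposure,
                    on=["risk", "location", "year", "sex", "age_lower", "age_upper"],
                )
                errs.append((((m["mean"] - m["true_mean"]) / m["true_mean"]) ** 2).mean())
            rmse[n] = np.sqrt(np.mean(errs))
        assert rmse[1000] < rmse[50]


class TestTwoPeriodWorlds:
    def test_unit_drift_equal_population_means_no_change(self):
        bundle = generate_two_period_world(WorldSpec(seed=13))
        t = bundle.ground_truth_exposure
        wide = t.pivot_table(
            index=["risk", "location", "sex", "age_lower"],
            columns="year", values="true_mean",
        )
        y1, y2 = sorted(wide.columns)
        assert np.allclose(wide[y1], wide[y2])
        env = bundle.envelopes.pivot_table(
            index=["outcome", "metric", "location", "sex", "age_lower"],
            columns="year", values="count",
        )
        assert np.allclose(env[y1], env[y2])

    def test_exposure_drift_applies_multiplicatively(self):
        bundle = generate_two_period_world(WorldSpec(seed=13), exposure_trend=1.01)
        t = bundle.ground_truth_exposure
        wide = t.pivot_table(
            index=["risk", "location", "sex", "age_lower"],
            columns="year", values="true_mean",
        )
        y1, y2 = sorted(wide.columns)
        assert np.allclose(wide[y2] / wide[y1], 1.01 ** (y2 - y1))

    def test_calibrated_world_reproduces_target_change(self):
        from dietcra.burden import pct_change
        from dietcra.pipeline import run_all

        bundle = generate_two_period_world(
            WorldSpec(seed=17), pop_growth=0.02, rate_trend=0.99
        )
        calibrated = calibrate_attributable_deaths(
            bundle, {1990: 37_465.0, 2013: 60_402.0}
        )
        result = run_all(calibrated, n_draws=2, seed=17)
        s = result.burden_summary.set_index(["metric", "year"])
        v1 = s.loc[("deaths", 1990), "count_point"]
        v2 = s.loc[("deaths", 2013), "count_point"]
        assert v1 == pytest.approx(37_465.0, rel=1e-9)
        assert round(pct_change(v1, v2), 1) == 61.2
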