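"""Survey pooling, the hierarchy cascade, and exposure utilities."""

import numpy as np
import pandas as pd
import pytest

from dietcra.exposure import (
    ExposureEstimate,
    Hierarchy,
    HierarchyNode,
    SurveyDatum,
    cascade_fit,
    data_representativeness,
    energy_adjust,
    estimate_exposure_surface,
    estimate_sodium_multiplier,
    fit_global,
)
from dietcra.risk_model import AgeGroup, ValidationError


def _datum(mean, se, sex="female", age=(25, 35), year=2013, loc="C1", cov=()):
    return SurveyDatum(
        location=loc, year=year, sex=sex, age_group=AgeGroup(*age),
        reported_mean=mean, standard_error=se, sample_size=100, covariates=cov,
    )


class TestFitGlobal:
    def test_matches_independent_wls_and_recovers_slope(self):
        rng = np.random.default_rng(5)
        n, beta = 200, 1.7
        z = rng.normal(0, 1, n)
        se = rng.uniform(0.3, 0.8, n)
        y = 10.0 + beta * z + rng.normal(0, se)
        data = [_datum(y[i], se[i], cov=(("z", z[i]),)) for i in range(n)]
        fit = fit_global(data, ["z"])
        # independent weighted-least-squares on the same matrix
        X = np.column_stack([np.ones(n), z])
        W = np.diag(1.0 / se**2)
        beta_hat = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        assert fit.coefficient("intercept") == pytest.approx(beta_hat[0], rel=1e-8)
        assert fit.coefficient("z") == pytest.approx(beta_hat[1], rel=1e-8)
        assert abs(fit.coefficient("z") - beta) < 3 * fit.standard_error("z")

    def test_identical_observations_collapse_to_intercept(self):
        data = [_datum(5.0, 1.0) for _ in range(4)]
        fit = fit_global(data)
        assert fit.column_names == ["intercept"]
        assert fit.coefficient("intercept") == pytest.approx(5.0)
        assert fit.residual_variance == 0.0

    def test_null_covariate_ci_coverage(self):
        """95% CI on a zero-effect covariate covers 0 in >= 90/100 replicates."""
        root = np.random.default_rng(42)
        hits = 0
        for _ in range(100):
            rng = np.random.default_rng(root.integers(2**31))
            n = 500
            z = rng.normal(0, 1, n)
            y = 3.0 + rng.normal(0, 0.5, n)
            data = [_datum(y[i], 0.5, cov=(("z", z[i]),)) for i in range(n)]
            lo, hi = fit_global(data, ["z"]).confidence_interval("z")
            hits += lo <= 0.0 <= hi
        assert hits >= 90

    def test_duplicated_covariate_names_collinear_column(self):
        rng = np.random.default_rng(0)
        data = [
            _datum(rng.normal(10, 1), 0.5, cov=(("a", v), ("b", v)))
            for v in rng.normal(0, 1, 30)
        ]
        with pytest.raises(ValidationError, match="b"):
            fit_global(data, ["a", "b"])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_global([_datum(5.0, 1.0)])


class TestCascadeFit:
    PARENT = ExposureEstimate(
        node="R1", level="region", posterior_mean=10.0, posterior_sd=2.0,
        source_level="region",
    )

    def test_no_local_data_inherits_parent(self):
        child = cascade_fit(self.PARENT, [], node="C1", level="country")
        assert child.posterior_mean == self.PARENT.posterior_mean
        assert child.posterior_sd == self.PARENT.posterior_sd
        assert child.source_level == "region"

    def test_equal_precision_average(self):
        child = cascade_fit(self.PARENT, [_datum(20.0, 2.0)], 1.0, node="C1",
                            level="country")
        assert child.posterior_mean == pytest.approx(15.0)
        assert child.source_level == "country"

    def test_abundant_local_data_dominates(self):
        data = [_datum(20.0 + 0.01 * i, 0.05) for i in range(50)]
        child = cascade_fit(self.PARENT, data, 1.0)
        means = np.array([d.reported_mean for d in data])
        ses = np.array([d.standard_error for d in data])
        w = 1 / ses**2
        local = float((w * means).sum() / w.sum())
        assert child.posterior_mean == pytest.approx(local, rel=0.01)

    def test_contraction_with_local_data(self):
        for ps in (0.5, 1.0, 4.0):
            child = cascade_fit(self.PARENT, [_datum(12.0, 3.0)], ps)
            assert child.posterior_sd < self.PARENT.posterior_sd / np.sqrt(ps)

    def test_invalid_prior_strength(self):
        with pytest.raises(ValidationError):
            cascade_fit(self.PARENT, [], prior_strength=0.0)


def _small_hierarchy():
    return Hierarchy(
        [
            HierarchyNode("global", "global"),
            HierarchyNode("SR1", "super_region", "global"),
            HierarchyNode("SR1-R1", "region", "SR1"),
            HierarchyNode("SR1-R1-C1", "country", "SR1-R1"),
            HierarchyNode("SR1-R1-C2", "country", "SR1-R1"),
        ]
    )


class TestHierarchy:
    def test_requires_single_global_root(self):
        with pytest.raises(ValidationError):
            Hierarchy([HierarchyNode("SR1", "super_region", "g")])

    def test_ancestor_chain(self):
        h = _small_hierarchy()
        assert h.ancestors("SR1-R1-C1") == ["SR1-R1", "SR1", "global"]
        assert h.countries() == ["SR1-R1-C1", "SR1-R1-C2"]

    def test_frame_round_trip(self):
        h = _small_hierarchy()
        back = Hierarchy.from_frame(h.to_frame())
        assert back.to_frame().equals(h.to_frame())


class TestExposureSurface:
    def test_no_data_country_inherits_ancestor_estimate(self):
        h = _small_hierarchy()
        surveys = pd.DataFrame(
            [
                {"location": "SR1-R1-C1", "year": 2013, "sex": "female",
                 "age_lower": 25.0, "age_upper": 35.0, "mean": 10.0, "se": 0.5},
                {"location": "SR1-R1-C1", "year": 2013, "sex": "female",
                 "age_lower": 25.0, "age_upper": 35.0, "mean": 11.0, "se": 0.5},
            ]
        )
        est = estimate_exposure_surface(surveys, h)
        by_loc = est.set_index("location")
        # the estimate for the no-data country was informed at region level
        assert by_loc.loc["SR1-R1-C2", "source_level"] == "region"
        assert by_loc.loc["SR1-R1-C1", "source_level"] == "country"
        # the no-data country inherits the pooled estimate of its ancestors
        assert by_loc.loc["SR1-R1-C2", "mean"] == pytest.approx(10.5, rel=0.05)

    def test_countries_with_data_recover_truth_better(self):
        """Countries with surveys beat no-data countries on RMSE vs truth."""
        from dietcra.pipeline import estimate_all_exposures
        from dietcra.synthetic import WorldSpec, generate_world

        bundle = generate_world(WorldSpec(seed=23))
        est = estimate_all_exposures(bundle)
        m = est.merge(
            bundle.ground_truth_exposure,
            on=["risk", "location", "year", "sex", "age_lower", "age_upper"],
        )
        covered = bundle.surveys.groupby("risk")["location"].apply(set).to_dict()
        m["with_data"] = [
            r["location"] in covered.get(r["risk"], set())
            for r in m.to_dict("records")
        ]
        rel_err = (m["mean"] - m["true_mean"]) / m["true_mean"]
        rmse = rel_err.pow(2).groupby(m["with_data"]).mean().pow(0.5)
        assert rmse[True] < rmse[False]


class TestEnergyAdjust:
    def test_uniform_energy_is_identity(self):
        out = energy_adjust([(90.0, 2000.0), (110.0, 2000.0)])
        assert np.allclose(out, [90.0, 110.0])

    def test_two_point_line_evaluated_at_target(self):
        out = energy_adjust([(90.0, 1800.0), (110.0, 2200.0)])
        assert np.allclose(out, [100.0, 100.0])

    def test_mean_preserving_identity_and_idempotence(self):
        rng = np.random.default_rng(3)
        energy = rng.uniform(1500, 2500, 50)
        intake = 40 + 0.03 * energy + rng.normal(0, 3, 50)
        adjusted = energy_adjust(list(zip(intake, energy)))
        slope, icept = np.polyfit(energy, intake, 1)
        assert adjusted.mean() == pytest.approx(icept + slope * 2000.0, rel=1e-10)
        again = energy_adjust([(a, 2000.0) for a in adjusted])
        assert np.allclose(again, adjusted)

    def test_non_positive_energy_rejected(self):
        with pytest.raises(ValidationError):
            energy_adjust([(90.0, 0.0), (110.0, 2200.0)])


class TestSodiumMultiplier:
    def test_exact_proportionality(self):
        pairs = [(d, 0.9 * d) for d in (1.0, 2.5, 4.0)]
        assert estimate_sodium_multiplier(pairs) == pytest.approx(0.9, rel=1e-12)

    def test_through_origin_slope_hand_computation(self):
        assert estimate_sodium_multiplier([(2, 1.7), (4, 3.5)]) == pytest.approx(0.87)

    def test_noisy_recovery_within_005(self):
        rng = np.random.default_rng(9)
        d = rng.uniform(1, 6, 100)
        u = 0.85 * d + rng.normal(0, 0.2, 100)
        u = np.abs(u) + 1e-6
        est = estimate_sodium_multiplier(list(zip(d, u)))
        assert abs(est - 0.85) < 0.05

    def test_non_positive_values_rejected(self):
        with pytest.raises(ValidationError):
            estimate_sodium_multiplier([(2.0, -1.0)])


class TestDataRepresentativeness:
    @pytest.mark.parametrize(
        "with_data,total,expected",
        [(17, 100, 0.17), (94, 100, 0.94), (0, 100, 0.0)],
    )
    def test_fraction_of_countries_with_data(self, with_data, total, expected):
        countries = {f"C{i}" for i in range(total)}
        covered = {f"C{i}" for i in range(with_data)}
        assert data_representativeness(covered, countries) == pytest.approx(expected)

    def test_empty_country_set_rejected(self):
        with pytest.raises(ValidationError):
            data_representativeness(set(), set())
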