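"""Domain types: registries, distributions, curves, TMRELs."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from dietcra.risk_model import (
    AgeGroup,
    CauseBurden,
    Direction,
    DrawSet,
    ExposureDistribution,
    MediationChain,
    RelativeRiskCurve,
    RiskFactor,
    Stratum,
    Tmrel,
    ValidationError,
    default_risk_registry,
    load_risk_registry,
    registry_to_config,
    validate_age_partition,
)


class TestRiskRegistry:
    def test_default_registry_has_the_14_gbd_risks(self):
        risks = default_risk_registry()
        assert len(risks) == 14
        by_cat = {}
        for r in risks:
            by_cat.setdefault(r.category, []).append(r.name)
        assert len(by_cat["food"]) == 8
        assert len(by_cat["nutrient"]) == 5
        assert by_cat["fibre"] == ["fibre"]

    def test_mediated_risks_are_flagged(self):
        risks = {r.name: r for r in default_risk_registry()}
        assert risks["sodium"].mediator == "sbp"
        assert risks["sugar-sweetened beverages"].mediator == "bmi"
        assert not risks["fruits"].mediated

    def test_empty_config_gives_empty_registry(self):
        assert load_risk_registry({"risks": []}) == []
        assert load_risk_registry({}) == []

    def test_round_trip_is_lossless(self):
        risks = default_risk_registry()
        assert load_risk_registry(registry_to_config(risks)) == risks

    @pytest.mark.parametrize(
        "config",
        [
            {"risks": [{"name": "a", "direction": "harmful_low"},
                       {"name": "a", "direction": "harmful_high"}]},
            {"risks": [{"name": "a", "direction": "sideways"}]},
            {"risks": [{"name": "a", "direction": "harmful_low", "mediator": "cortisol"}]},
        ],
        ids=["duplicate-name", "unknown-direction", "unknown-mediator"],
    )
    def test_invalid_configs_rejected(self, config):
        with pytest.raises(ValidationError):
            load_risk_registry(config)


class TestAgeGroupsAndStrata:
    def test_partition_accepts_contiguous_groups(self):
        validate_age_partition([AgeGroup(25, 35), AgeGroup(35, 45), AgeGroup(45, 55)])

    def test_partition_rejects_gap_and_overlap(self):
        with pytest.raises(ValidationError):
            validate_age_partition([AgeGroup(25, 35), AgeGroup(40, 50)])
        with pytest.raises(ValidationError):
            validate_age_partition([AgeGroup(25, 40), AgeGroup(35, 50)])

    def test_degenerate_age_group_rejected(self):
        with pytest.raises(ValidationError):
            AgeGroup(35, 35)

    def test_stratum_is_hashable_value_object(self):
        s1 = Stratum("ETH", AgeGroup(25, 35), "female", 2013)
        s2 = Stratum("ETH", AgeGroup(25, 35), "female", 2013)
        assert s1 == s2 and hash(s1) == hash(s2)


class TestExposureDistribution:
    @pytest.mark.parametrize("family", ["lognormal", "gamma", "truncated_normal"])
    def test_density_integrates_to_one_on_support(self, family):
        dist = ExposureDistribution(mean=3.5, sd=1.2, family=family)
        l, u = dist.support
        total, _ = quad(dist.pdf, l, u, limit=200)
        assert abs(total - 1.0) < 1e-6

    @given(
        family=st.sampled_from(["lognormal", "gamma", "truncated_normal"]),
        mean=st.floats(0.5, 500.0),
        cv=st.floats(0.05, 0.6),
        q=st.floats(0.01, 0.99),
    )
    def test_quantile_inverts_cdf(self, family, mean, cv, q):
        dist = ExposureDistribution(mean=mean, sd=cv * mean, family=family)
        x = dist.ppf(q)
        assert dist.ppf(dist.cdf(x)) == pytest.approx(x, rel=1e-8, abs=1e-8)

    def test_default_support_is_central_998(self):
        dist = ExposureDistribution(mean=2.0, sd=0.5)
        assert dist.cdf(dist.support[0]) == pytest.approx(0.0, abs=1e-12)
        assert dist.cdf(dist.support[1]) == pytest.approx(1.0, abs=1e-12)

    def test_serialisation_round_trip(self):
        dist = ExposureDistribution(mean=2.0, sd=0.5, family="gamma")
        back = ExposureDistribution.from_dict(dist.to_dict())
        assert back.to_dict() == dist.to_dict()

    @pytest.mark.parametrize(
        "kwargs",
        [dict(mean=-1.0, sd=0.5), dict(mean=2.0, sd=-0.1),
         dict(mean=2.0, sd=0.5, support=(3.0, 1.0))],
        ids=["negative-mean", "negative-sd", "inverted-support"],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            ExposureDistribution(**kwargs)

    def test_degenerate_distribution_has_no_density(self):
        dist = ExposureDistribution(mean=2.0, sd=0.0)
        assert dist.degenerate
        with pytest.raises(ValidationError):
            dist.pdf(2.0)


class TestRelativeRiskCurve:
    def test_rr_is_one_at_reference(self):
        rf = RiskFactor("sodium", Direction.harmful_high)
        curve = RelativeRiskCurve(rf, "stroke", np.log(1.3))
        assert curve.rr(2.0, 2.0) == 1.0

    def test_rr_positive_everywhere(self):
        rf = RiskFactor("fruits", Direction.harmful_low)
        curve = RelativeRiskCurve(rf, "ihd", np.log(1.3) / 300, cap_at_tmrel=False)
        x = np.linspace(0, 1000, 101)
        assert np.all(curve.rr(x, 300.0) > 0)

    def test_capped_curve_plateaus_on_no_risk_side(self):
        rf = RiskFactor("fruits", Direction.harmful_low)
        curve = RelativeRiskCurve(rf, "ihd", np.log(1.3) / 300)
        assert np.all(curve.rr(np.array([300.0, 400.0, 900.0]), 300.0) == 1.0)
        assert curve.rr(200.0, 300.0) > 1.0


class TestMediationChain:
    def _chain(self, slope):
        rf = RiskFactor("sodium", Direction.harmful_high, mediator="sbp")
        mrr = RelativeRiskCurve(rf, "ihd", np.log(1.25) / 10.0)
        return MediationChain(rf, "sbp", slope, mrr)

    def test_composed_rr_is_one_at_reference(self):
        assert self._chain(2.0).rr(2.0, 2.0) == 1.0

    def test_zero_slope_gives_unit_rr_everywhere(self):
        chain = self._chain(0.0)
        assert np.all(chain.rr(np.linspace(0, 10, 21), 2.0) == 1.0)


class TestTmrel:
    def test_bounds_are_plus_minus_twenty_percent(self):
        rf = RiskFactor("fruits", Direction.harmful_low)
        t = Tmrel(rf, optimal_mean=300.0)
        assert t.lower == pytest.approx(240.0, rel=1e-15)
        assert t.upper == pytest.approx(360.0, rel=1e-15)

    def test_samples_stay_in_band(self):
        rf = RiskFactor("fruits", Direction.harmful_low)
        t = Tmrel(rf, optimal_mean=100.0)
        draws = t.sample(np.random.default_rng(0), 5000)
        assert draws.min() >= 80.0 and draws.max() <= 120.0
        assert draws.min() < 81.0 and draws.max() > 119.0  # approaches bounds


class TestCauseBurdenAndDraws:
    def test_negative_count_rejected(self):
        s = Stratum("ETH", AgeGroup(25, 35), "female", 2013)
        with pytest.raises(ValidationError):
            CauseBurden("cvd", "deaths", s, count=-1.0, population=1000.0)
        with pytest.raises(ValidationError):
            CauseBurden("cvd", "steps", s, count=1.0, population=1000.0)

    def test_drawset_is_one_dimensional_ordered(self):
        ds = DrawSet(values=[1.0, 2.0, 3.0], seed=1)
        assert ds.n_draws == len(ds) == 3
        with pytest.raises(ValidationError):
            DrawSet(values=np.ones((2, 2)))
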