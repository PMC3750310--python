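"""Monte Carlo engine: determinism, propagation, summaries, risk."""

import math

import numpy as np
import pytest

from cadexpo.distributions import (
    FittedDistribution,
    lognormal_from_mean_median,
    point_mass,
)
from cadexpo.montecarlo import (
    FoodInput,
    PopulationModel,
    build_population_model,
    model_from_json,
    model_to_json,
    risk_below,
    simulate,
    summarize,
)
from cadexpo.tables import ValidationError


def _degenerate_model(food_records):
    """All inputs point masses at the table means; smoking term fixed at the
    published population mean 3.93 ug/day (via a degenerate cigarettes draw)."""
    foods = [
        FoodInput(
            name=r.food_name,
            conc=point_mass(r.conc_mean) if r.conc_mean > 0 else point_mass(1e-12),
            intake=point_mass(r.intake_mean) if r.intake_mean > 0 else point_mass(1e-12),
        )
        for r in food_records
    ]
    return PopulationModel(
        foods=foods,
        smoking_prevalence=1.0,
        cigarettes=point_mass(3.93 / 1.5),
        tobacco_conc=point_mass(1.5),
        cigarette_mass=1.0,
        water=0.03,
        stratum="smokers",
    )


class TestSimulate:
    def test_degenerate_inputs_reproduce_point_estimate(self, food_records):
        result = simulate(_degenerate_model(food_records), 100, seed=1)
        assert np.allclose(result.draws, 16.73, atol=0.05)

    def test_single_lognormal_mean_within_three_se(self):
        model = PopulationModel(
            foods=[
                FoodInput(
                    "x",
                    conc=point_mass(1.0),
                    intake=FittedDistribution("lognormal", 0.0, 1.0),
                )
            ],
            smoking_prevalence=0.0,
            cigarettes=point_mass(1.0),
            tobacco_conc=point_mass(1.5),
            water=0.0,
            stratum="nonsmokers",
        )
        result = simulate(model, 100_000, seed=7)
        expected = math.exp(0.5)
        se = result.draws.std(ddof=1) / math.sqrt(result.n)
        assert abs(result.draws.mean() - expected) < 3 * se

    def test_seed_determinism(self, food_records, config):
        model = build_population_model(food_records, config, "total")
        a = simulate(model, 5000, seed=42)
        b = simulate(model, 5000, seed=42)
        assert np.array_equal(a.draws, b.draws)
        for key in a.input_draws:
            assert np.array_equal(a.input_draws[key], b.input_draws[key])

    def test_zero_iterations_rejected(self, food_records, config):
        model = build_population_model(food_records, config, "total")
        with pytest.raises(ValidationError):
            simulate(model, 0, seed=1)

    def test_mean_linearity(self, food_records, config):
        # simulated total mean equals the sum of input-term means within 3 MC SE
        model = build_population_model(food_records, config, "total")
        result = simulate(model, 100_000, seed=11)
        analytic = (
            sum(f.conc.mean() * f.intake.mean() for f in model.foods)
            + model.smoking_prevalence
            * model.cigarettes.mean()
            * model.tobacco_conc.mean()
            * model.cigarette_mass
            + model.water
        )
        se = result.draws.std(ddof=1) / math.sqrt(result.n)
        assert abs(result.draws.mean() - analytic) < 3 * se


class TestRiskBelow:
    def test_all_draws_below(self, food_records):
        result = simulate(_degenerate_model(food_records), 50, seed=2)
        assert risk_below(result, 49.5) == 1.0

    def test_total_model_reconstruction(self):
        d = lognormal_from_mean_median(23.05, 18.24)
        model = PopulationModel(
            foods=[FoodInput("total", conc=point_mass(1.0), intake=d)],
            smoking_prevalence=0.0,
            cigarettes=point_mass(1.0),
            tobacco_conc=point_mass(1.5),
            water=1e-12,
            stratum="nonsmokers",
        )
        result = simulate(model, 100_000, seed=3)
        assert risk_below(result, 49.5) == pytest.approx(d.cdf(49.5), abs=0.005)
        assert risk_below(result, 49.5) == pytest.approx(0.928, abs=0.005)

    def test_women_model_reconstruction(self):
        d = lognormal_from_mean_median(14.05, 10.62)
        model = PopulationModel(
            foods=[FoodInput("total", conc=point_mass(1.0), intake=d)],
            smoking_prevalence=0.0,
            cigarettes=point_mass(1.0),
            tobacco_conc=point_mass(1.5),
            water=1e-12,
            stratum="nonsmokers",
        )
        result = simulate(model, 100_000, seed=4)
        assert risk_below(result, 49.5) == pytest.approx(0.980, abs=0.003)


class TestSummarize:
    def test_tiny_sample(self):
        from cadexpo.montecarlo import SimulationResult

        res = SimulationResult(
            n=5, seed=0, stratum="total", draws=np.array([1.0, 2, 3, 4, 5])
        )
        s = summarize(res)
        assert s.mean == 3.0
        assert s.median == 3.0
        assert s.min == 1.0 and s.max == 5.0

    def test_lognormal_median_matches_analytic(self):
        d = FittedDistribution("lognormal", 2.9036, 0.6840)
        model = PopulationModel(
            foods=[FoodInput("x", conc=point_mass(1.0), intake=d)],
            smoking_prevalence=0.0,
            cigarettes=point_mass(1.0),
            tobacco_conc=point_mass(1.5),
            water=1e-12,
            stratum="nonsmokers",
        )
        s = summarize(simulate(model, 100_000, seed=5))
        assert s.median == pytest.approx(18.24, abs=0.3)
        assert s.p5 <= s.median <= s.p95
        assert s.min <= s.p5 and s.p95 <= s.max

    def test_point_mass_summary(self, food_records):
        s = summarize(simulate(_degenerate_model(food_records), 100, seed=6))
        assert s.std == pytest.approx(0.0, abs=1e-12)
        assert s.p5 == pytest.approx(s.p95)


class TestStratumCoherence:
    def test_mixture_risk_between_strata(self, food_records, config):
        n = 50_000
        smokers = simulate(
            build_population_model(food_records, config, "smokers"), n, seed=8
        )
        nonsmokers = simulate(
            build_population_model(food_records, config, "nonsmokers"), n, seed=8
        )
        total = simulate(
            build_population_model(food_records, config, "total"), n, seed=8
        )
        lo = risk_below(smokers, config.ptdi)
        hi = risk_below(nonsmokers, config.ptdi)
        assert lo <= risk_below(total, config.ptdi) <= hi

    def test_invalid_stratum_prevalence_rejected(self, food_records, config):
        model = build_population_model(food_records, config, "smokers")
        assert model.smoking_prevalence == 1.0
        with pytest.raises(ValidationError):
            PopulationModel(
                foods=model.foods,
                smoking_prevalence=0.5,
                cigarettes=model.cigarettes,
                tobacco_conc=model.tobacco_conc,
                stratum="smokers",
            )


class TestModelSerialization:
    def test_json_round_trip_preserves_simulation(self, food_records, config):
        model = build_population_model(food_records, config, "women")
        again = model_from_json(model_to_json(model))
        a = simulate(model, 2000, seed=9)
        b = simulate(again, 2000, seed=9)
        assert np.array_equal(a.draws, b.draws)
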