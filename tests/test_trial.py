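"""Trial execution: cohorts, adherence, discontinuation, endpoint rules."""
from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from uratetrial import trial
from uratetrial.pkpd import InvalidInputError
from uratetrial.trial import (
    AdherenceParams,
    ArmResult,
    Cohort,
    PopulationSpec,
    apply_inclusion,
    response_rate,
    sample_dosing_history,
    sample_population,
    simulate_arm,
)


def _manual_cohort(baselines) -> Cohort:
    baselines = np.asarray(baselines, dtype=float)
    n = baselines.size
    return Cohort(
        baseline_sua=baselines,
        weight=np.full(n, 70.0),
        age=np.full(n, 50.0),
        p_implementation=np.full(n, 1.0),
        eta={},
    )


class TestSamplePopulation:
    def test_same_seed_reproduces_cohort(self):
        spec, adh = PopulationSpec(), AdherenceParams()
        c1 = sample_population(spec, adh, 200, seed=9)
        c2 = sample_population(spec, adh, 200, seed=9)
        np.testing.assert_array_equal(c1.baseline_sua, c2.baseline_sua)
        np.testing.assert_array_equal(c1.p_implementation, c2.p_implementation)
        for key in c1.eta:
            np.testing.assert_array_equal(c1.eta[key], c2.eta[key])

    def test_zero_variance_gives_identical_subjects(self):
        spec = PopulationSpec(
            baseline_sua_sigma=0.0, weight_sigma=0.0, age_sd=1e-12,
            iiv={"cl": 0.0},
        )
        adh = AdherenceParams(implementation_dispersion=0.0)
        c = sample_population(spec, adh, 50, seed=1)
        assert np.ptp(c.baseline_sua) == 0.0
        assert np.ptp(c.weight) == 0.0
        assert np.ptp(c.p_implementation) == 0.0
        assert np.all(c.eta["cl"] == 0.0)

    def test_mean_implementation_probability_is_090(self):
        spec, adh = PopulationSpec(), AdherenceParams()
        c = sample_population(spec, adh, 10_000, seed=123)
        assert c.p_implementation.mean() == pytest.approx(0.9, abs=0.01)

    def test_invalid_size_rejected(self):
        with pytest.raises(InvalidInputError):
            sample_population(PopulationSpec(), AdherenceParams(), 0, seed=1)


class TestInclusion:
    def test_strict_threshold_boundaries(self):
        cohort = _manual_cohort([7.5, 8.0, 9.1])
        kept6 = apply_inclusion(cohort, 6.0)
        assert list(kept6.baseline_sua) == [7.5, 8.0, 9.1]
        kept8 = apply_inclusion(cohort, 8.0)
        # 7.5 excluded; the boundary value 8.0 is excluded too (strict >)
        assert list(kept8.baseline_sua) == [9.1]

    def test_idempotent_and_order_preserving(self):
        cohort = _manual_cohort([9.0, 6.5, 8.2, 10.0])
        once = apply_inclusion(cohort, 8.0)
        twice = apply_inclusion(once, 8.0)
        np.testing.assert_array_equal(once.baseline_sua, twice.baseline_sua)
        assert list(once.baseline_sua) == [9.0, 8.2, 10.0]

    def test_zero_threshold_keeps_everyone(self):
        cohort = _manual_cohort([7.5, 8.0])
        assert len(apply_inclusion(cohort, 0.0)) == 2

    def test_empty_result_warns(self):
        cohort = _manual_cohort([5.0])
        with pytest.warns(UserWarning):
            apply_inclusion(cohort, 12.0)


class TestDosingHistory:
    def test_perfect_implementation_no_dropout_takes_all(self):
        adh = AdherenceParams(weibull_scale=1e12)
        hist = sample_dosing_history(adh, 1.0, 300.0, 60, seed=4)
        assert hist.taken.sum() == 60
        assert hist.dropout_day is None

    def test_zero_implementation_takes_nothing(self):
        adh = AdherenceParams()
        hist = sample_dosing_history(adh, 0.0, 300.0, 60, seed=4)
        assert hist.taken.sum() == 0

    def test_no_doses_after_dropout(self):
        adh = AdherenceParams(weibull_shape=0.5, weibull_scale=5.0)
        for seed in range(20):
            hist = sample_dosing_history(adh, 1.0, 300.0, 40, seed=seed)
            if hist.dropout_day is not None:
                assert hist.taken[hist.dropout_day:].sum() == 0

    def test_dropout_free_fraction_matches_weibull_survival(self):
        shape, scale = 0.5, 400.0
        adh = AdherenceParams(weibull_shape=shape, weibull_scale=scale)
        rng = np.random.default_rng(2024)
        n = 10_000
        dropout = trial._sample_dropout_days(adh, n, rng)
        for t in (7, 30, 90, 182):
            surv = np.exp(-((t / scale) ** shape))
            frac = float((dropout > t).mean())
            se = np.sqrt(surv * (1 - surv) / n)
            assert abs(frac - surv) <= 3 * se


class TestArmSimulation:
    def test_same_seed_bit_identical(self, default_model, short_design):
        cohort = apply_inclusion(
            sample_population(default_model.population, default_model.adherence, 40, seed=8),
            short_design.inclusion_threshold,
        )
        r1 = simulate_arm(short_design, 1, cohort, default_model, seed=77)
        r2 = simulate_arm(short_design, 1, cohort, default_model, seed=77)
        np.testing.assert_array_equal(r1.final_sua, r2.final_sua)
        np.testing.assert_array_equal(r1.dropout_day, r2.dropout_day)

    def test_dropouts_revert_to_baseline_exactly(self, default_model, short_design):
        heavy = dataclasses.replace(
            default_model,
            adherence=AdherenceParams(weibull_shape=0.5, weibull_scale=10.0),
        )
        cohort = apply_inclusion(
            sample_population(heavy.population, heavy.adherence, 60, seed=3),
            short_design.inclusion_threshold,
        )
        res = simulate_arm(short_design, 0, cohort, heavy, seed=5)
        assert res.dropped.any()
        np.testing.assert_array_equal(
            res.final_sua[res.dropped], res.baseline_sua[res.dropped]
        )

    def test_all_dropout_day_one_with_high_baselines_gives_zero_response(
        self, default_model, short_design
    ):
        instant = dataclasses.replace(
            default_model,
            adherence=AdherenceParams(weibull_shape=1.0, weibull_scale=1e-3),
        )
        cohort = _manual_cohort([8.5, 9.0, 10.0, 9.5])
        res = simulate_arm(short_design, 1, cohort, instant, seed=1)
        assert res.dropped.all()
        assert response_rate(res) == 0.0

    def test_response_monotone_in_implementation_mean(self, default_model):
        from uratetrial.config import default_designs

        design = default_designs(duration=56)[0]
        rates = []
        for mean in (0.5, 0.7, 0.9, 1.0):
            model = dataclasses.replace(
                default_model,
                adherence=AdherenceParams(
                    implementation_mean=mean, weibull_scale=1e12
                ),
            )
            cohort = apply_inclusion(
                sample_population(model.population, model.adherence, 80, seed=17),
                design.inclusion_threshold,
            )
            res = simulate_arm(design, 1, cohort, model, seed=55)
            rates.append(response_rate(res))
        # non-decreasing up to Monte Carlo error on an 80-subject cohort
        assert all(b >= a - 0.05 for a, b in zip(rates, rates[1:]))
        assert rates[-1] > rates[0]


class TestResponseRate:
    def _result(self, finals, duration=28):
        finals = np.asarray(finals, dtype=float)
        n = finals.size
        return ArmResult(
            baseline_sua=np.full(n, 9.0),
            final_sua=finals,
            responder=finals < trial.RESPONSE_THRESHOLD,
            dropout_day=np.full(n, duration + 1),
            duration=duration,
        )

    def test_simple_proportion(self):
        finals = np.array([5.0] * 36 + [7.0] * 64)
        assert response_rate(self._result(finals)) == pytest.approx(0.36)

    def test_all_responders(self):
        assert response_rate(self._result([4.0, 5.0, 5.9])) == 1.0

    def test_exactly_six_is_nonresponder(self):
        assert response_rate(self._result([6.0])) == 0.0

    def test_empty_arm_rejected(self):
        with pytest.raises(InvalidInputError):
            response_rate(self._result(np.empty(0)))

    def test_inconsistent_flags_rejected(self):
        with pytest.raises(InvalidInputError):
            ArmResult(
                baseline_sua=np.array([9.0]),
                final_sua=np.array([5.0]),
                responder=np.array([False]),
                dropout_day=np.array([99]),
                duration=28,
            )
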