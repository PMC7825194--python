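"""PK/PD engine: closed forms, ODE oracles, calibration, and invariants."""
from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from uratetrial import pkpd
from uratetrial.pkpd import (
    DosingHistory,
    InvalidInputError,
    PDParams,
    PKParams,
    SubjectCovariates,
    calibrate_baseline,
    concentration_profile,
    individualize_params,
    simulate_urate,
    steady_state_urate,
)

ONE_COMP = PKParams(model_order="one_compartment", ka=8.0, cl=25.0, v1=40.0, f=0.8)
TWO_COMP = PKParams(
    model_order="two_compartment", ka=25.0, cl=250.0, v1=35.0, f=0.85, q=100.0, v2=40.0
)
CHAIN = PDParams(
    kin=2000.0, k_hx_x=3.0, k_x_ua=3.0, clr_hx=50.0, clr_x=50.0, clr_ua=13.0,
    v_hx=50.0, v_x=50.0, v_ua=40.0, imax=0.9, ic50=2.0, emax_x=0.5, ec50_x=2.0,
)


class TestParamValidation:
    def test_rejects_nonpositive_rates(self):
        with pytest.raises(InvalidInputError):
            PKParams(model_order="one_compartment", ka=-1.0, cl=25.0, v1=40.0)
        with pytest.raises(InvalidInputError):
            PDParams(**{**CHAIN.__dict__, "clr_ua": 0.0})

    def test_two_compartment_fields_enforced(self):
        with pytest.raises(InvalidInputError):
            PKParams(model_order="two_compartment", ka=1.0, cl=10.0, v1=40.0)
        with pytest.raises(InvalidInputError):
            PKParams(model_order="one_compartment", ka=1.0, cl=10.0, v1=40.0, q=5.0, v2=20.0)

    def test_imax_bounds(self):
        with pytest.raises(InvalidInputError):
            PDParams(**{**CHAIN.__dict__, "imax": 1.2})

    def test_covariates_must_be_positive(self):
        with pytest.raises(InvalidInputError):
            SubjectCovariates(baseline_sua=8.0, weight=-70.0, age=50.0)


class TestIndividualize:
    def test_identity_at_reference_with_zero_eta(self):
        cov = SubjectCovariates(baseline_sua=8.0, weight=70.0, age=50.0)
        pk, pd = individualize_params(ONE_COMP, CHAIN, cov)
        assert pk == ONE_COMP
        for name in ("kin", "k_hx_x", "clr_ua", "v_ua", "imax", "ic50"):
            assert getattr(pd, name) == pytest.approx(getattr(CHAIN, name))

    def test_allometric_weight_scaling_on_clearance(self):
        cov = SubjectCovariates(baseline_sua=8.0, weight=140.0, age=50.0)
        pk, pd = individualize_params(ONE_COMP, CHAIN, cov)
        assert pk.cl == pytest.approx(ONE_COMP.cl * 2.0**0.75, rel=1e-12)
        assert pk.v1 == pytest.approx(ONE_COMP.v1 * 2.0, rel=1e-12)
        assert pd.clr_ua == pytest.approx(CHAIN.clr_ua * 2.0**0.75, rel=1e-12)

    def test_lognormal_random_effect_doubles_ka(self):
        cov = SubjectCovariates(baseline_sua=8.0, weight=70.0, age=50.0)
        pk, _ = individualize_params(ONE_COMP, CHAIN, cov, eta_pk={"ka": math.log(2.0)})
        assert pk.ka == pytest.approx(2.0 * ONE_COMP.ka, rel=1e-12)

    def test_nonfinite_eta_rejected(self):
        cov = SubjectCovariates(baseline_sua=8.0, weight=70.0, age=50.0)
        with pytest.raises(InvalidInputError):
            individualize_params(ONE_COMP, CHAIN, cov, eta_pk={"ka": float("nan")})

    def test_array_individualisation_matches_scalar_path(self, default_model):
        from uratetrial.trial import Cohort, _individualize_arrays

        rng = np.random.default_rng(5)
        n = 5
        cohort = Cohort(
            baseline_sua=rng.uniform(7, 10, n),
            weight=rng.uniform(60, 110, n),
            age=rng.uniform(30, 75, n),
            p_implementation=np.full(n, 0.9),
            eta={"cl": rng.normal(0, 0.2, n), "ic50": rng.normal(0, 0.3, n)},
        )
        drug = default_model.drugs["allopurinol"]
        pd_pop = default_model.arm_pd("allopurinol")
        pk_arr, pd_arr = _individualize_arrays(
            drug.pk, pd_pop, cohort, default_model.covariates
        )
        for i in range(n):
            pk_i, pd_i = individualize_params(
                drug.pk,
                pd_pop,
                cohort.subject(i),
                eta_pk={"cl": cohort.eta["cl"][i]},
                eta_pd={"ic50": cohort.eta["ic50"][i]},
                model=default_model.covariates,
            )
            assert pk_arr["cl"][i] == pytest.approx(pk_i.cl, rel=1e-12)
            assert pd_arr["ic50"][i] == pytest.approx(pd_i.ic50, rel=1e-12)
            assert pd_arr["clr_ua"][i] == pytest.approx(pd_i.clr_ua, rel=1e-12)


def _ode_concentration(pk: PKParams, dose_days, dose: float, eval_times):
    """Numerical ODE oracle for oral linear PK (independent of the closed form)."""
    n_extra = 1 if pk.model_order == "one_compartment" else 2

    # amounts in depot / central / (peripheral)
    def rhs_amounts(t, y):
        a, a1 = y[0], y[1]
        out = [-pk.ka * a, pk.ka * a - pk.cl * a1 / pk.v1]
        if n_extra == 2:
            a2 = y[2]
            out[1] += -pk.q * a1 / pk.v1 + pk.q * a2 / pk.v2
            out.append(pk.q * a1 / pk.v1 - pk.q * a2 / pk.v2)
        return out

    y = np.zeros(1 + n_extra)
    t_prev = 0.0
    events = sorted(dose_days) + [None]
    samples = np.zeros(len(eval_times))
    eval_times = np.asarray(eval_times, dtype=float)
    for day in events:
        t_next = float(day) if day is not None else float(eval_times.max())
        if t_next > t_prev:
            mask = (eval_times >= t_prev) & (eval_times <= t_next)
            sol = solve_ivp(
                rhs_amounts, (t_prev, t_next), y,
                t_eval=np.unique(np.concatenate([eval_times[mask], [t_next]])),
                rtol=1e-10, atol=1e-12, method="LSODA",
            )
            for t, col in zip(sol.t, sol.y.T):
                hit = np.isclose(eval_times, t)
                samples[hit] = col[1] / pk.v1
            y = sol.y[:, -1]
        if day is not None:
            y[0] += pk.f * dose
        t_prev = t_next
    return samples


class TestConcentration:
    def test_no_doses_gives_zero(self):
        hist = DosingHistory(dose_amount=300.0, taken=np.zeros(10, dtype=np.int8))
        t = np.linspace(0, 10, 50)
        assert np.all(concentration_profile(ONE_COMP, hist, t) == 0.0)

    @pytest.mark.parametrize("pk", [ONE_COMP, TWO_COMP], ids=["one_comp", "two_comp"])
    def test_single_dose_matches_numerical_ode(self, pk):
        taken = np.zeros(6, dtype=np.int8)
        taken[0] = 1
        hist = DosingHistory(dose_amount=300.0, taken=taken)
        t = np.linspace(0.05, 5.0, 40)
        analytic = concentration_profile(pk, hist, t)
        numeric = _ode_concentration(pk, [0], 300.0, t)
        scale = analytic.max()
        assert np.max(np.abs(analytic - numeric)) / scale < 1e-3

    def test_superposition_of_two_doses(self):
        taken2 = np.zeros(8, dtype=np.int8)
        taken2[[0, 3]] = 1
        hist2 = DosingHistory(dose_amount=300.0, taken=taken2)
        t = np.linspace(0, 8, 81)
        both = concentration_profile(ONE_COMP, hist2, t)
        single = np.zeros_like(t)
        for day in (0, 3):
            tk = np.zeros(8, dtype=np.int8)
            tk[day] = 1
            single += concentration_profile(
                ONE_COMP, DosingHistory(dose_amount=300.0, taken=tk), t
            )
        np.testing.assert_allclose(both, single, rtol=1e-12, atol=1e-15)

    @pytest.mark.parametrize("pk", [ONE_COMP, TWO_COMP], ids=["one_comp", "two_comp"])
    def test_internal_dose_grid_matches_profile(self, pk):
        """The batched amplitude-recursion grid equals direct superposition."""
        rng = np.random.default_rng(0)
        duration = 14
        taken = (rng.random(duration) < 0.8).astype(np.int8)
        hist = DosingHistory(dose_amount=120.0, taken=taken)
        dt = 0.1
        t_grid = np.linspace(0, duration, 2 * round(duration / dt) + 1)
        direct = concentration_profile(pk, hist, t_grid)
        rates, coefs = pk.disposition_terms(120.0)
        grid = pkpd._conc_grid_from_doses(
            rates[None, :], coefs[None, :], taken[None, :], duration, dt
        )[0]
        np.testing.assert_allclose(grid, direct, rtol=1e-9, atol=1e-12)

    def test_equal_absorption_elimination_degenerate_case(self):
        pk = PKParams(model_order="one_compartment", ka=0.625, cl=25.0, v1=40.0)
        taken = np.zeros(4, dtype=np.int8)
        taken[0] = 1
        hist = DosingHistory(dose_amount=300.0, taken=taken)
        t = np.linspace(0.05, 4, 30)
        analytic = concentration_profile(pk, hist, t)
        numeric = _ode_concentration(pk, [0], 300.0, t)
        assert np.max(np.abs(analytic - numeric)) / analytic.max() < 1e-3


class TestSteadyStateAndCalibration:
    def test_calibrated_baseline_reproduced(self):
        pd = calibrate_baseline(CHAIN, 8.0)
        assert steady_state_urate(pd, 0.0) == pytest.approx(8.0, rel=1e-12)

    def test_kin_linear_in_baseline(self):
        pd1 = calibrate_baseline(CHAIN, 4.0)
        pd2 = calibrate_baseline(CHAIN, 8.0)
        assert pd2.kin == pytest.approx(2.0 * pd1.kin, rel=1e-12)

    def test_complete_inhibition_drives_urate_to_zero(self):
        pd = PDParams(**{**CHAIN.__dict__, "imax": 1.0})
        assert steady_state_urate(pd, 1e9) == pytest.approx(0.0, abs=1e-6)

    def test_half_maximal_effect_at_ic50(self):
        inhib = CHAIN.inhibition(CHAIN.ic50)
        assert 1.0 - inhib == pytest.approx(1.0 - CHAIN.imax / 2.0, rel=1e-12)

    def test_steady_state_decreasing_in_concentration(self):
        conc = np.linspace(0, 20, 15)
        ss = np.array([steady_state_urate(CHAIN, c) for c in conc])
        assert np.all(np.diff(ss) <= 0)


class TestSimulateUrate:
    def test_zero_concentration_holds_baseline(self):
        series = simulate_urate(CHAIN, 0.0, duration=30, baseline=8.0)
        assert series.shape == (30,)
        np.testing.assert_allclose(series, 8.0, rtol=1e-3)

    def test_constant_concentration_reaches_analytic_steady_state(self):
        pd = calibrate_baseline(CHAIN, 8.0)
        # slowest turnover: urate, t1/2 = ln2 / (clr_ua / v_ua) ~ 2.1 days
        t_half = math.log(2.0) / (pd.clr_ua / pd.v_ua)
        duration = int(math.ceil(10 * t_half)) + 1
        series = simulate_urate(pd, 1.5, duration=duration)
        target = steady_state_urate(pd, 1.5)
        assert abs(series[-1] - target) / target < 0.01

    def test_no_effect_drug_leaves_baseline(self):
        inert = PDParams(**{**CHAIN.__dict__, "imax": 0.0, "emax_x": 0.0})
        series = simulate_urate(inert, 50.0, duration=20, baseline=9.0)
        np.testing.assert_allclose(series, 9.0, rtol=1e-3)

    def test_terminal_sua_monotone_in_dose(self):
        pd = calibrate_baseline(CHAIN, 8.5)
        pk = ONE_COMP
        finals = []
        for dose in (0.0, 50.0, 150.0, 300.0, 600.0):
            taken = np.ones(25, dtype=np.int8)
            hist = DosingHistory(dose_amount=dose, taken=taken) if dose else DosingHistory(
                dose_amount=1.0, taken=np.zeros(25, dtype=np.int8)
            )
            t_grid = np.linspace(0, 25, 2 * 250 + 1)
            conc = concentration_profile(pk, hist, t_grid)
            finals.append(simulate_urate(pd, conc, duration=25)[-1])
        assert all(b <= a + 1e-9 for a, b in zip(finals, finals[1:]))

    def test_response_classification_matches_analytic_oracle(self):
        """Under constant exposure, responder status agrees with the steady state."""
        rng = np.random.default_rng(42)
        pd = calibrate_baseline(CHAIN, 9.0)
        for conc in rng.uniform(0.1, 10.0, 20):
            target = steady_state_urate(pd, conc)
            if abs(target - 6.0) / 6.0 < 0.02:
                continue  # boundary cases are decided by transients
            final = simulate_urate(pd, float(conc), duration=40)[-1]
            assert (final < 6.0) == (target < 6.0)

    def test_bad_grid_length_rejected(self):
        with pytest.raises(InvalidInputError):
            simulate_urate(CHAIN, np.zeros(17), duration=10)
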