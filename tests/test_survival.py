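"""Survival-curve models: closed forms, invariants, fitting, model ranking."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bnct_tcp import (
    SurvivalDataset,
    SurvivalParamsLQ,
    SurvivalParamsLQL,
    SurvivalParamsPLQ,
    SurvivalParamsUSC,
    compare_models,
    fit_survival_model,
    ln_survival,
    ln_survival_lq,
    ln_survival_lql,
    ln_survival_plq,
    ln_survival_usc,
    read_survival_data,
    standard_error_of_estimate,
    usc_transition_dose,
    write_survival_data,
)
from bnct_tcp.synthetic import SurvivalSimConfig, simulate_survival_data

LQ = SurvivalParamsLQ(alpha=0.2111, beta=0.0890)


class TestClosedForms:
    @pytest.mark.parametrize(
        "d,expected",
        [(0.0, 0.0), (1.0, -0.3001), (2.0, -0.7782)],
    )
    def test_lq_hand_values(self, d, expected):
        assert ln_survival_lq(d, LQ) == pytest.approx(expected, abs=1e-9)

    def test_usc_linear_branch(self, scc):
        # -(20 - Dq)/D0 on the multi-target line
        assert ln_survival_usc(20.0, scc) == pytest.approx(-18.8911, abs=1e-3)

    def test_usc_branches_agree_at_transition(self, scc):
        lq = -(scc.alpha * scc.dt + scc.beta * scc.dt**2)
        mt = -(scc.dt - scc.dq) / scc.d0
        assert abs(lq - mt) < 1e-3 * abs(lq)

    def test_lql_hand_value(self):
        p = SurvivalParamsLQL(alpha=0.2, beta=0.05, dt=5.0, gamma=0.7)
        assert ln_survival_lql(10.0, p) == pytest.approx(-5.75, abs=1e-12)

    def test_lql_branches_coincide_at_dt(self):
        p = SurvivalParamsLQL.from_lq(0.3, 0.04, 6.0)
        assert ln_survival_lql(p.dt, p) == pytest.approx(
            ln_survival_lq(p.dt, SurvivalParamsLQ(0.3, 0.04)), abs=1e-12
        )

    def test_plq_hand_value(self):
        p = SurvivalParamsPLQ(alpha=0.2111, beta=0.0890, gamma=0.1)
        assert ln_survival_plq(10.0, p) == pytest.approx(-5.5055, abs=1e-9)

    @pytest.mark.parametrize(
        "fn,params",
        [
            (ln_survival_lq, LQ),
            (ln_survival_usc, "scc"),
            (ln_survival_lql, SurvivalParamsLQL.from_lq(0.2, 0.05, 5.0)),
            (ln_survival_plq, SurvivalParamsPLQ(0.2, 0.05, 0.1)),
        ],
    )
    def test_zero_dose_and_monotone(self, fn, params, scc):
        if params == "scc":
            params = scc
        grid = np.linspace(0.0, 30.0, 301)
        y = fn(grid, params)
        assert y[0] == 0.0
        assert np.all(np.diff(y) <= 1e-12)

    @pytest.mark.parametrize(
        "fn,params",
        [
            (ln_survival_lq, LQ),
            (ln_survival_lql, SurvivalParamsLQL.from_lq(0.2, 0.05, 5.0)),
            (ln_survival_plq, SurvivalParamsPLQ(0.2, 0.05, 0.1)),
        ],
    )
    def test_negative_dose_rejected(self, fn, params):
        with pytest.raises(ValueError):
            fn(-1.0, params)

    @given(d=st.floats(0.0, 4.0))
    def test_lql_equals_lq_below_dt(self, d):
        p = SurvivalParamsLQL.from_lq(0.25, 0.03, 4.0)
        assert ln_survival_lql(d, p) == ln_survival_lq(d, SurvivalParamsLQ(0.25, 0.03))

    @given(d=st.floats(0.0, 30.0))
    def test_plq_gamma_zero_reduces_to_lq(self, d):
        p = SurvivalParamsPLQ(alpha=0.2111, beta=0.0890, gamma=0.0)
        assert ln_survival_plq(d, p) == pytest.approx(ln_survival_lq(d, LQ), rel=1e-12)


class TestTransitionDose:
    def test_published_scc_value(self):
        assert usc_transition_dose(0.2111, 0.9603, 1.8588) == pytest.approx(
            4.6628, abs=1e-3
        )

    def test_alpha_zero_limit(self):
        assert usc_transition_dose(0.0, 1.0, 1.5) == pytest.approx(3.0)

    def test_hand_value(self):
        assert usc_transition_dose(0.5, 1.0, 1.0) == pytest.approx(4.0)

    def test_no_transition_when_alpha_d0_too_large(self):
        with pytest.raises(ValueError):
            usc_transition_dose(1.2, 1.0, 1.0)


class TestParamInvariants:
    def test_usc_rejects_inconsistent_dt(self):
        with pytest.raises(ValueError):
            SurvivalParamsUSC(alpha=0.2111, beta=0.0890, d0=0.9603, dq=1.8588, dt=6.0)

    def test_usc_lql_round_trip(self):
        # exact smooth-join parametrization round-trips through LQL form
        p = SurvivalParamsUSC.from_smooth_join(0.2111, 0.9603, 1.8588)
        back = p.to_lql().to_usc()
        assert back.alpha == pytest.approx(p.alpha, rel=1e-12)
        grid = np.linspace(0, 25, 100)
        np.testing.assert_allclose(
            ln_survival_usc(grid, back), ln_survival_usc(grid, p), rtol=1e-9, atol=1e-9
        )

    def test_lql_gamma_must_be_lq_slope(self):
        with pytest.raises(ValueError):
            SurvivalParamsLQL(alpha=0.2, beta=0.05, dt=5.0, gamma=0.5)


def _noiseless(params, grid=None):
    grid = np.linspace(0.5, 12, 24) if grid is None else grid
    return SurvivalDataset(dose=grid, survival=np.exp(ln_survival(grid, params)))


class TestFitting:
    def test_noiseless_lq_recovered_exactly(self):
        truth = SurvivalParamsLQ(alpha=0.3, beta=0.03)
        fit = fit_survival_model(_noiseless(truth), "lq")
        assert fit.params.alpha == pytest.approx(0.3, abs=1e-6)
        assert fit.params.beta == pytest.approx(0.03, abs=1e-6)
        assert fit.see < 1e-10

    def test_noiseless_usc_recovered_within_1pct(self, scc):
        fit = fit_survival_model(_noiseless(scc), "usc")
        for name in ("alpha", "beta", "d0", "dq"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(scc, name), rel=0.01
            ), name

    def test_fit_idempotence_on_model_predictions(self, scc):
        first = fit_survival_model(_noiseless(scc), "usc")
        second = fit_survival_model(_noiseless(first.params), "usc")
        for name in ("alpha", "beta", "d0", "dq"):
            assert getattr(second.params, name) == pytest.approx(
                getattr(first.params, name), abs=1e-6, rel=1e-4
            )

    def test_insufficient_points_rejected(self):
        data = SurvivalDataset(dose=[1, 2, 3], survival=[0.7, 0.4, 0.2])
        with pytest.raises(ValueError, match="at least"):
            fit_survival_model(data, "usc")

    def test_usc_dt_is_derived_not_free(self, scc):
        fit = fit_survival_model(_noiseless(scc), "usc")
        p = fit.params
        assert p.dt == pytest.approx(usc_transition_dose(p.alpha, p.d0, p.dq), rel=1e-9)
        assert p.beta == pytest.approx(
            (1 - p.alpha * p.d0) ** 2 / (4 * p.dq * p.d0), rel=1e-9
        )


class TestSEE:
    def test_perfect_fit_gives_zero(self, scc):
        data = _noiseless(scc)
        assert standard_error_of_estimate(data, "usc", scc) == pytest.approx(0, abs=1e-12)

    def test_symmetric_residuals_closed_form(self):
        # three points, LQ params, residuals (+r, -r, 0): SEE = r*sqrt(2) at N-p=1
        p = SurvivalParamsLQ(alpha=0.2, beta=0.02)
        d = np.array([1.0, 2.0, 3.0])
        r = 0.05
        s = np.exp(ln_survival_lq(d, p) + np.array([r, -r, 0.0]))
        data = SurvivalDataset(dose=d, survival=s)
        assert standard_error_of_estimate(data, "lq", p) == pytest.approx(
            r * math.sqrt(2), rel=1e-9
        )

    def test_too_few_points_rejected(self):
        p = SurvivalParamsLQ(alpha=0.2, beta=0.02)
        data = SurvivalDataset(dose=[1.0, 2.0], survival=[0.8, 0.5])
        with pytest.raises(ValueError):
            standard_error_of_estimate(data, "lq", p)

    def test_lq_misfits_usc_tail(self, scc):
        data = simulate_survival_data(SurvivalSimConfig(noise_sigma=0.05, seed=11))
        see_lq = fit_survival_model(data, "lq").see
        see_usc = fit_survival_model(data, "usc").see
        assert see_lq > see_usc


class TestCompareModels:
    def test_usc_first_on_usc_data(self):
        data = simulate_survival_data(SurvivalSimConfig(noise_sigma=0.1, seed=7))
        ranked = compare_models(data, n_restarts=6)
        assert ranked[0].model_kind == "usc"
        sees = [r.see for r in ranked]
        # ascending up to the tie tolerance (ties resolved by parameter count)
        assert all(b >= a - 1e-8 for a, b in zip(sees, sees[1:]))

    def test_lq_wins_tiebreak_on_pure_lq_data(self):
        truth = SurvivalParamsLQ(alpha=0.3, beta=0.03)
        ranked = compare_models(_noiseless(truth), n_restarts=6)
        sees = {r.model_kind: r.see for r in ranked}
        # nested models reach the same (near-zero) SEE; fewest parameters wins
        assert ranked[0].model_kind == "lq"
        assert sees["lq"] < 1e-8

    def test_three_point_dataset_rejected(self):
        data = SurvivalDataset(dose=[2, 5, 9], survival=[0.5, 0.1, 0.01])
        with pytest.raises(ValueError):
            compare_models(data)

    def test_usc_lql_tie_is_exact_family_equivalence(self):
        data = simulate_survival_data(SurvivalSimConfig(noise_sigma=0.1, seed=3))
        ranked = compare_models(data, n_restarts=6)
        sees = {r.model_kind: r.see for r in ranked}
        assert sees["usc"] == pytest.approx(sees["lql"], abs=1e-8)


class TestDatasetIO:
    def test_round_trip(self, tmp_path, scc):
        data = simulate_survival_data(SurvivalSimConfig(noise_sigma=0.1, seed=2))
        path = tmp_path / "surv.csv"
        write_survival_data(data, path)
        back = read_survival_data(path)
        np.testing.assert_allclose(back.dose, data.dose)
        np.testing.assert_allclose(back.survival, data.survival)

    def test_tab_delimited_with_comments(self, tmp_path):
        path = tmp_path / "surv.tsv"
        path.write_text("# clonogenic assay\ndose_Gy\tsurvival_fraction\n0\t1.0\n2\t0.5\n4\t0.1\n")
        data = read_survival_data(path)
        assert len(data) == 3

    def test_survival_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SurvivalDataset(dose=[1, 2], survival=[0.5, 1.2])

    def test_duplicate_doses_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            SurvivalDataset(dose=[1, 1, 2], survival=[0.5, 0.5, 0.2])
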