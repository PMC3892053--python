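import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pkpdkit import (
    ConcentrationProfile,
    DegenerateParameterError,
    EstimationError,
    InputError,
    OralPKParameters,
    fit_oral_pk,
    nca_iv,
    oral_concentration,
    terminal_halflife_sparse,
)


def make_profile(route, dose, times, conc, **kw):
    return ConcentrationProfile(
        subject_id="s1", route=route, dose=dose,
        times=tuple(times), concentrations=tuple(conc), **kw,
    )


class TestOralConcentration:
    def test_zero_at_and_before_tlag(self, em_pk):
        c = oral_concentration(em_pk, 2.0, [0.0, 0.1, em_pk.tlag])
        assert np.all(c == 0.0)

    def test_nonnegative_everywhere(self, em_pk):
        t = np.linspace(0, 100, 5000)
        assert np.all(oral_concentration(em_pk, 2.0, t) >= 0)

    def test_tmax_derivative_zero(self, em_pk):
        # numerical-differentiation oracle at the analytic peak time
        tmax = em_pk.tlag + np.log(em_pk.k01 / em_pk.k10) / (em_pk.k01 - em_pk.k10)
        h = 1e-5
        c = oral_concentration(em_pk, 2.0, [tmax - h, tmax, tmax + h])
        deriv = (c[2] - c[0]) / (2 * h)
        assert abs(deriv) < 1e-4 * c[1]
        assert c[1] >= c[0] and c[1] >= c[2]

    def test_auc_matches_closed_form(self, em_pk):
        t = np.linspace(0, 400, 200_000)
        auc = np.trapezoid(oral_concentration(em_pk, 2.0, t), t)
        expected = 2.0 * 1000.0 / (em_pk.v_over_f * em_pk.k10)
        assert auc == pytest.approx(expected, rel=0.01)

    def test_unimodal(self, em_pk):
        t = np.linspace(0, 48, 2000)
        c = oral_concentration(em_pk, 2.0, t)
        d = np.diff(c)
        sign_changes = np.count_nonzero(np.diff(np.sign(d[np.abs(d) > 1e-12])))
        assert sign_changes <= 1

    def test_degenerate_rates_rejected(self):
        with pytest.raises(DegenerateParameterError):
            OralPKParameters(v_over_f=1.0, k01=0.5, k10=0.5)

    def test_nonpositive_dose_rejected(self, em_pk):
        with pytest.raises(InputError):
            oral_concentration(em_pk, 0.0, [1.0])


class TestFitOralPK:
    TIMES = (0.5, 1.0, 1.5, 4.0, 6.0, 9.0, 15.0, 30.0, 48.0)

    def test_noise_free_round_trip(self, em_pk):
        obs = oral_concentration(em_pk, 2.0, self.TIMES)
        prof = make_profile("oral", 2.0, self.TIMES, obs)
        est, diag = fit_oral_pk(prof, (2,))
        assert diag.converged
        for got, true in [
            (est.v_over_f, em_pk.v_over_f), (est.k01, em_pk.k01),
            (est.k10, em_pk.k10), (est.tlag, em_pk.tlag),
        ]:
            assert got == pytest.approx(true, rel=1e-3)

    def test_aic_prefers_biexponential(self, em_pk, rng):
        obs = oral_concentration(em_pk, 2.0, self.TIMES)
        noisy = obs * np.exp(rng.normal(0, 0.01, len(obs)))
        prof = make_profile("oral", 2.0, self.TIMES, noisy)
        _, diag = fit_oral_pk(prof, (2, 3))
        assert diag.n_exponentials == 2
        assert diag.aic_by_candidate[2] <= diag.aic_by_candidate[3]

    def test_too_few_points(self, em_pk):
        t = (1.0, 2.0, 3.0)
        obs = oral_concentration(em_pk, 2.0, t)
        with pytest.raises(InputError):
            fit_oral_pk(make_profile("oral", 2.0, t, obs))

    def test_iv_route_rejected(self, em_pk):
        obs = oral_concentration(em_pk, 2.0, self.TIMES)
        with pytest.raises(InputError):
            fit_oral_pk(make_profile("iv", 2.0, self.TIMES, obs))

    def test_flip_flop_constraint(self, em_pk):
        obs = oral_concentration(em_pk, 2.0, self.TIMES)
        est, _ = fit_oral_pk(make_profile("oral", 2.0, self.TIMES, obs), (2,))
        assert est.k01 > est.k10

    def test_bql_exclusion(self, em_pk):
        # values below LOQ (incl. pre-dose zero) are flagged and excluded
        times = (0.0,) + self.TIMES
        obs = oral_concentration(em_pk, 2.0, times)
        prof = make_profile("oral", 2.0, times, obs)
        assert prof.bql_flags[0]
        t_q, _ = prof.quantifiable()
        assert 0.0 not in t_q
        est, _ = fit_oral_pk(prof, (2,))
        assert est.k10 == pytest.approx(em_pk.k10, rel=1e-3)


class TestNCA:
    def test_monoexponential_closed_form(self):
        lam, c0 = 0.25, 1800.0
        t = np.arange(0.25, 48.0, 0.25)
        prof = make_profile("iv", 2.0, t, c0 * np.exp(-lam * t))
        res = nca_iv(prof)
        assert res.auc_0_inf == pytest.approx(c0 / lam, rel=0.01)
        assert res.half_life == pytest.approx(np.log(2) / lam, rel=0.01)
        assert res.clearance == pytest.approx(2000.0 / (c0 / lam), rel=0.01)
        assert res.v_z == pytest.approx(res.clearance / res.lambda_z, rel=1e-9)

    def test_scaling_homogeneity(self):
        lam, c0 = 0.25, 1800.0
        t = np.arange(0.25, 48.0, 0.25)
        p1 = make_profile("iv", 2.0, t, c0 * np.exp(-lam * t))
        p2 = make_profile("iv", 2.0, t, 2 * c0 * np.exp(-lam * t))
        r1, r2 = nca_iv(p1), nca_iv(p2)
        assert r2.auc_0_inf == pytest.approx(2 * r1.auc_0_inf, rel=1e-9)
        assert r2.clearance == pytest.approx(r1.clearance / 2, rel=1e-9)
        assert r2.half_life == pytest.approx(r1.half_life, rel=1e-9)

    def test_two_compartment_lambda_z(self):
        # eigenvalue oracle: slowest eigen-rate of the micro-rate matrix
        k10, k12, k21 = 0.5, 0.3, 0.2
        A = np.array([[-(k10 + k12), k21], [k12, -k21]])
        eig = np.sort(np.abs(np.linalg.eigvals(A)))
        lam_slow, lam_fast = eig
        # biexponential with those eigen-rates
        t = np.arange(0.1, 60.0, 0.1)
        c = 1500.0 * np.exp(-lam_fast * t) + 500.0 * np.exp(-lam_slow * t)
        res = nca_iv(make_profile("iv", 2.0, t, c))
        assert res.lambda_z == pytest.approx(lam_slow, rel=0.02)

    def test_rising_terminal_phase_error(self):
        t = (1.0, 2.0, 4.0, 8.0, 16.0)
        c = (100.0, 120.0, 150.0, 190.0, 240.0)
        with pytest.raises(EstimationError):
            nca_iv(make_profile("iv", 2.0, t, c))

    def test_extrapolation_warning(self):
        # sampling stops early: large extrapolated tail
        lam, c0 = 0.05, 1000.0
        t = np.array([0.5, 1.0, 2.0, 3.0, 4.0, 5.0])
        res = nca_iv(make_profile("iv", 2.0, t, c0 * np.exp(-lam * t)))
        assert res.auc_extrapolated_fraction > 0.20
        assert res.extrapolation_warning

    def test_time_unit_invariance(self):
        # consistent h -> min conversion leaves CL (per kg per h) derivable
        lam, c0 = 0.25, 1800.0
        t_h = np.arange(0.25, 48.0, 0.25)
        res_h = nca_iv(make_profile("iv", 2.0, t_h, c0 * np.exp(-lam * t_h)))
        res_min = nca_iv(make_profile("iv", 2.0, t_h * 60, c0 * np.exp(-lam * t_h)))
        assert res_min.half_life == pytest.approx(res_h.half_life * 60, rel=1e-6)
        assert res_min.clearance == pytest.approx(res_h.clearance / 60, rel=1e-6)


class TestSparseHalflife:
    def test_exact_log_linear(self):
        t = np.array([6.0, 8.0, 10.0, 24.0])
        hl = terminal_halflife_sparse(t, 100 * np.exp(-0.2 * t))
        assert hl == pytest.approx(np.log(2) / 0.2, rel=1e-9)

    def test_monte_carlo_median_within_3pct(self):
        t = np.array([6.0, 8.0, 10.0, 24.0])
        true_hl = np.log(2) / 0.2
        rng = np.random.default_rng(11)
        est = []
        for _ in range(500):
            c = 100 * np.exp(-0.2 * t) * np.exp(rng.normal(0, 0.05, 4))
            est.append(terminal_halflife_sparse(t, c))
        assert np.median(est) == pytest.approx(true_hl, rel=0.03)

    def test_rising_profile_error(self):
        with pytest.raises(EstimationError):
            terminal_halflife_sparse([6, 8, 10, 24], [10, 20, 30, 40])

    def test_nonpositive_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            hl = terminal_halflife_sparse([6, 8, 10, 24], [100, 66.0, 0.0, 2.7])
        assert hl > 0

    def test_single_usable_point_error(self):
        with pytest.warns(UserWarning), pytest.raises(EstimationError):
            terminal_halflife_sparse([6, 8], [100.0, 0.0])

    def test_matches_nca_on_monoexponential(self):
        lam, c0 = 0.3, 900.0
        t = np.arange(0.5, 48.0, 0.5)
        c = c0 * np.exp(-lam * t)
        hl_sparse = terminal_halflife_sparse(t, c)
        hl_nca = nca_iv(make_profile("iv", 2.0, t, c)).half_life
        assert hl_sparse == pytest.approx(hl_nca, rel=1e-6)


@settings(max_examples=25, deadline=None)
@given(
    v=st.floats(0.5, 5.0), k10=st.floats(0.05, 1.0),
    ratio=st.floats(1.5, 20.0), tlag=st.floats(0.0, 1.0),
    dose=st.floats(0.5, 8.0),
)
def test_property_bateman_nonnegative_and_auc(v, k10, ratio, tlag, dose):
    p = OralPKParameters(v_over_f=v, k01=k10 * ratio, k10=k10, tlag=tlag)
    t = np.linspace(0, 30 / k10, 4000)
    c = oral_concentration(p, dose, t)
    assert np.all(c >= 0)
    assert np.trapezoid(c, t) == pytest.approx(p.auc_0_inf(dose), rel=0.02)
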