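import numpy as np
import pytest

from pkpdkit import (
    ENDPOINT_MODEL_KIND,
    EffectTimeCourse,
    IndirectResponseModelKind,
    IndirectResponseParameters,
    InputError,
    fit_turnover,
    hill_fraction,
    oral_concentration,
    simulate_turnover,
)
from pkpdkit.synthetic_data import SCHEDULES

K = IndirectResponseModelKind


class TestHillFraction:
    def test_zero_concentration(self):
        assert hill_fraction(0.0, 0.71, 239.4, 4.74) == 0.0

    def test_half_max_at_c50(self):
        assert hill_fraction(239.4, 0.71, 239.4, 4.74) == pytest.approx(0.71 / 2)

    def test_em_creeping_speed_row_at_twice_c50(self):
        # direct arithmetic: cap * 2^n / (1 + 2^n)
        cap, c50, n = 0.71, 239.4, 4.74
        expected = cap * 2**n / (1 + 2**n)
        got = hill_fraction(2 * c50, cap, c50, n)
        assert got == pytest.approx(expected, rel=1e-12)
        assert 0.5 * cap < got < cap

    def test_strictly_increasing_and_bounded(self):
        c = np.linspace(0, 5000, 400)
        f = hill_fraction(c, 0.9, 200.0, 3.0)
        assert np.all(np.diff(f) > 0)
        assert np.all(f < 0.9)

    def test_large_c_approaches_cap(self):
        assert hill_fraction(1e12, 0.5, 100.0, 6.0) == pytest.approx(0.5, rel=1e-6)


class TestSimulateTurnover:
    @pytest.mark.parametrize("kind", list(K))
    def test_zero_concentration_holds_baseline(self, kind, pd_sets):
        p = pd_sets["creeping_speed"]
        t = np.linspace(0, 48, 30)
        sim = simulate_turnover(kind, p, lambda tt: 0.0, t)
        assert np.allclose(sim.response, p.baseline, rtol=1e-6)

    def test_stimulate_kout_saturated_steady_state(self, pd_sets):
        p = pd_sets["body_temperature"]  # kin 41.30, kout 1.04, Emax 0.04
        sim = simulate_turnover(K.STIMULATE_KOUT, p, lambda tt: 1e9,
                                np.linspace(0, 80, 50))
        expected = p.kin / (p.kout * (1 + p.effect_cap))
        assert sim.response[-1] == pytest.approx(expected, rel=1e-6)
        # baseline ~39.7, dropping ~3.8% at full effect
        assert p.baseline == pytest.approx(39.7, abs=0.05)
        assert 1 - expected / p.baseline == pytest.approx(0.0385, abs=0.002)

    def test_lameness_baseline_matches_scale_max(self, pd_sets):
        p = pd_sets["lameness_score"]  # kin 5.34, kout 1.08
        assert p.baseline == pytest.approx(4.944, abs=0.001)
        assert round(p.baseline) == 5

    @pytest.mark.parametrize("kind,endpoint", [
        (K.STIMULATE_KOUT, "body_temperature"),
        (K.INHIBIT_KOUT, "creeping_speed"),
        (K.INHIBIT_KIN, "lameness_score"),
    ])
    def test_washout_returns_to_baseline(self, kind, endpoint, pd_sets, em_pk):
        p = pd_sets[endpoint]
        t_end = em_pk.tmax + 10 * np.log(2) / em_pk.k10
        sim = simulate_turnover(
            kind, p,
            lambda tt: float(oral_concentration(em_pk, 2.0, [tt])[0]),
            np.linspace(0, t_end, 60),
        )
        assert abs(sim.response[-1] / p.baseline - 1) < 1e-4

    def test_inhibit_kout_bounded_above(self, pd_sets):
        p = pd_sets["creeping_speed"]
        bound = p.kin / (p.kout * (1 - p.effect_cap))
        sim = simulate_turnover(K.INHIBIT_KOUT, p, lambda tt: 1e9,
                                np.linspace(0, 100, 200))
        assert np.all(np.asarray(sim.response) <= bound * (1 + 1e-9))

    def test_inhibit_kin_bounded_below_by_zero(self, pd_sets):
        p = pd_sets["lameness_score"]
        sim = simulate_turnover(K.INHIBIT_KIN, p, lambda tt: 1e9,
                                np.linspace(0, 100, 200))
        assert np.all(np.asarray(sim.response) >= 0)

    def test_piecewise_constant_matches_linear_ode_closed_form(self, pd_sets):
        # dR/dt = a - b R with constant coefficients per segment
        p = pd_sets["creeping_speed"]
        segments = [(0.0, 5.0, 0.0), (5.0, 10.0, 500.0), (10.0, 20.0, 50.0)]

        def conc_fn(t):
            for lo, hi, c in segments:
                if lo <= t < hi:
                    return c
            return segments[-1][2]

        times = np.linspace(0, 20, 81)
        sim = simulate_turnover(K.INHIBIT_KOUT, p, conc_fn, times, rtol=1e-10)
        r = p.baseline
        expected = []
        for t_prev, t_now in zip([0.0] + list(times), times):
            # advance segment-by-segment through [t_prev, t_now]
            t = t_prev
            while t < t_now - 1e-12:
                for lo, hi, c in segments:
                    if lo <= t < hi:
                        step_end = min(hi, t_now)
                        h = hill_fraction(c, p.effect_cap, p.c50, p.n)
                        b = p.kout * (1 - h)
                        rinf = p.kin / b
                        r = rinf + (r - rinf) * np.exp(-b * (step_end - t))
                        t = step_end
                        break
                else:
                    t = t_now
            expected.append(r)
        assert np.allclose(sim.response, expected, rtol=2e-6, atol=1e-8)

    def test_monotone_in_dose(self, pd_sets, em_pk):
        t_check = 4.0
        for endpoint, p in pd_sets.items():
            kind = ENDPOINT_MODEL_KIND[endpoint]
            effects = []
            for dose in (0.25, 1.0, 4.0):
                sim = simulate_turnover(
                    kind, p,
                    lambda tt, d=dose: float(oral_concentration(em_pk, d, [tt])[0]),
                    [t_check],
                )
                effects.append(abs(sim.response[-1] - p.baseline))
            assert effects[0] <= effects[1] + 1e-9 <= effects[2] + 2e-9

    def test_imax_above_one_rejected(self):
        p = IndirectResponseParameters(kin=1.0, kout=1.0, effect_cap=1.5,
                                       c50=100.0, n=2.0)
        with pytest.raises(InputError):
            simulate_turnover(K.INHIBIT_KOUT, p, lambda tt: 0.0, [0, 1])


class TestFitTurnover:
    def _course(self, endpoint, params, conc_fn, times):
        sim = simulate_turnover(ENDPOINT_MODEL_KIND[endpoint], params, conc_fn, times)
        t_minus = 0.0 if endpoint == "lameness_score" else 1.0
        return EffectTimeCourse(
            subject_id="d1", endpoint=endpoint, times=tuple(times),
            values=tuple(sim.response), t_minus=t_minus, t_plus=params.baseline,
        )

    @pytest.mark.parametrize("endpoint", [
        "body_temperature", "creeping_speed", "lameness_score", "vertical_force",
    ])
    def test_noise_free_round_trip(self, endpoint, pd_sets, em_conc_fn):
        true = pd_sets[endpoint]
        course = self._course(endpoint, true, em_conc_fn, SCHEDULES["pd_dense"])
        est, diag = fit_turnover(course, em_conc_fn, ENDPOINT_MODEL_KIND[endpoint])
        assert diag.converged
        assert est.kin == pytest.approx(true.kin, rel=0.01)
        assert est.kout == pytest.approx(true.kout, rel=0.01)
        assert est.n == pytest.approx(true.n, rel=0.01)
        assert est.c50 == pytest.approx(true.c50, rel=0.05)
        if endpoint != "lameness_score":
            assert est.effect_cap == pytest.approx(true.effect_cap, rel=0.01)

    def test_lameness_cap_fixed_at_one(self, pd_sets, em_conc_fn):
        course = self._course("lameness_score", pd_sets["lameness_score"],
                              em_conc_fn, SCHEDULES["pd_dense"])
        est, diag = fit_turnover(course, em_conc_fn, K.INHIBIT_KIN)
        assert est.effect_cap == 1.0
        assert diag.parameter_cis["effect_cap"] == (1.0, 1.0, 1.0)

    def test_endpoint_kind_mismatch(self, pd_sets, em_conc_fn):
        course = self._course("creeping_speed", pd_sets["creeping_speed"],
                              em_conc_fn, SCHEDULES["pd_dense"])
        with pytest.raises(InputError):
            fit_turnover(course, em_conc_fn, K.STIMULATE_KOUT)

    def test_too_few_observations(self, pd_sets, em_conc_fn):
        course = self._course("creeping_speed", pd_sets["creeping_speed"],
                              em_conc_fn, (2.0, 4.0, 9.0))
        with pytest.raises(InputError):
            fit_turnover(course, em_conc_fn, K.INHIBIT_KOUT)

    def test_cis_bracket_estimates(self, pd_sets, em_conc_fn, rng):
        true = pd_sets["creeping_speed"]
        times = SCHEDULES["pd_dense"]
        sim = simulate_turnover(K.INHIBIT_KOUT, true, em_conc_fn, times)
        vals = np.asarray(sim.response) + rng.normal(0, 0.01, len(times))
        course = EffectTimeCourse("d1", "creeping_speed", tuple(times),
                                  tuple(vals), t_minus=3.0, t_plus=true.baseline)
        est, diag = fit_turnover(course, em_conc_fn, K.INHIBIT_KOUT)
        for lo, mid, hi in diag.parameter_cis.values():
            assert lo <= mid <= hi
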