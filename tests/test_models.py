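"""Structural WBC models: rate laws, initial conditions, trajectories."""

import math
from dataclasses import replace

import numpy as np
import pytest
import scipy.integrate

import cytara as ct
from cytara.models import (_make_fast_rhs, initial_state, maturation_rate,
                           mean_maturation_time, pd_effect, proliferation_rate,
                           rhs, rhs_pd, saturation)
from cytara.pk import HOURS_PER_DAY, PKSolution
from cytara.predict import steady_state_params

ALL_MODELS = list(ct.MODELS)


@pytest.fixture(scope="module")
def params(consts):
    return steady_state_params(
        ct.PDParameters(b=5.0, slope=4.0, k_tr=0.25, gamma=0.6), consts)


class TestEffectFunctions:
    def test_zero_amount_zero_effect(self, consts):
        assert pd_effect(0.0, 3.0, consts.c_v) == 0.0

    def test_unit_effect_threshold(self, consts):
        """E crosses 1 exactly where c_V x1 = e^(1/slope) - 1."""
        slope = 0.7
        x1 = (math.exp(1.0 / slope) - 1.0) / consts.c_v
        assert pd_effect(x1, slope, consts.c_v) == pytest.approx(1.0, rel=1e-12)

    def test_closed_form(self):
        assert pd_effect(1.0, 0.2, 1.0) == pytest.approx(0.2 * math.log(2))

    def test_saturation_values(self, consts):
        assert saturation(0.0, consts.c_v) == 1.0
        assert saturation((math.e - 1) / consts.c_v, consts.c_v) == pytest.approx(2.0)
        x = np.linspace(0, 500, 40)
        s = np.array([saturation(v, consts.c_v) for v in x])
        assert np.all(np.diff(s) > 0)

    def test_negative_amount_rejected(self, consts):
        with pytest.raises(ValueError):
            pd_effect(-1.0, 1.0, consts.c_v)
        with pytest.raises(ValueError):
            saturation(-1.0, consts.c_v)


class TestRateLaws:
    @pytest.mark.parametrize("name", ALL_MODELS)
    def test_drug_free_homeostasis_rate(self, name, params, consts):
        """At x1=0 and the baseline state, F = k_tr in every variant."""
        spec = ct.get_model(name)
        bbm = params.b_bm(consts)
        f = proliferation_rate(spec, params, consts, 0.0, bbm, bbm, params.b)
        assert f == pytest.approx(params.k_tr, rel=1e-12)

    @pytest.mark.parametrize("slope", [0.3, 0.7, 1.5, 4.0])
    def test_sign_law(self, slope, consts):
        """F < 0 exactly when c_V x1 exceeds e^(1/slope) - 1 (reference model)."""
        spec = ct.get_model("M5")
        p = steady_state_params(
            ct.PDParameters(b=5.0, slope=slope, k_tr=0.25, gamma=0.6), consts)
        thresh = (math.exp(1.0 / slope) - 1.0) / consts.c_v
        bbm = p.b_bm(consts)
        for factor in [0.2, 0.5, 0.9, 1.1, 2.0, 5.0]:
            f = proliferation_rate(spec, p, consts, factor * thresh, bbm, bbm, 4.0)
            assert (f < 0) == (factor > 1.0)

    def test_secondary_effect_amplifies_suppression(self, params, consts):
        """Below baseline with drug present, |F| is larger under the
        gamma-scaled variant than under the reference model."""
        bbm = params.b_bm(consts)
        for x1 in [50.0, 200.0, 1000.0]:
            for xma in [0.5, 2.0, 4.0]:  # all below B = 5
                f5 = proliferation_rate(ct.get_model("M5"), params, consts, x1, bbm, bbm, xma)
                f10 = proliferation_rate(ct.get_model("M10"), params, consts, x1, bbm, bbm, xma)
                assert abs(f10) > abs(f5)

    def test_direct_kill_net_rate(self, params, consts):
        e = pd_effect(100.0, params.slope, consts.c_v)
        fb = (params.b / 4.0) ** params.gamma
        f = proliferation_rate(ct.get_model("M6"), params, consts, 100.0,
                               10.0, 10.0, 4.0)
        assert f == pytest.approx(params.k_tr * fb - e, rel=1e-12)

    def test_maturation_rates(self, params, consts):
        assert maturation_rate(ct.get_model("M5"), params, consts, 300.0) == params.k_tr
        assert maturation_rate(ct.get_model("M7"), params, consts, 0.0) == params.k_tr
        x1 = (math.e - 1) / consts.c_v  # S = 2
        assert maturation_rate(ct.get_model("M7"), params, consts, x1) == \
            pytest.approx(params.k_tr / 2.0)


class TestInitialConditions:
    def test_steady_state_values(self, consts):
        p = ct.PDParameters(b=5.0, slope=1.0, k_tr=consts.k_ma / 2.0, gamma=0.5)
        y = initial_state(ct.get_model("M3"), p, consts)
        np.testing.assert_allclose(y, [10.0, 10.0, 5.0])

    def test_free_initial_count_changes_derivative_sign(self, consts):
        """With x_ma(0) = B0 != B the circulating derivative at t0 is
        k_tr*B_bm - k_ma*B0, i.e. k_ma*(B - B0)."""
        spec = ct.get_model("M4")
        for b0 in (3.0, 8.0):
            p = ct.PDParameters(b=5.0, slope=1.0, k_tr=0.25, gamma=0.5, b0=b0)
            y = initial_state(spec, p, consts)
            dy = rhs_pd(spec, p, consts, 0.0, y)
            np.testing.assert_allclose(dy[1], 0.0, atol=1e-12)  # transit at rest
            assert dy[-1] == pytest.approx(consts.k_ma * (5.0 - b0), rel=1e-12)

    def test_missing_parameters_rejected(self, consts):
        p = ct.PDParameters(b=5.0, slope=1.0, k_tr=0.25, gamma=0.5)
        with pytest.raises(ValueError):
            initial_state(ct.get_model("M4"), p, consts)
        with pytest.raises(ValueError):
            initial_state(ct.get_model("M5"), p, consts)

    def test_estimated_init_reduces_to_steady_state(self, consts):
        p = ct.PDParameters(b=5.0, slope=1.0, k_tr=0.25, gamma=0.5)
        full = replace(p, b0=5.0, xpr0=p.b_bm(consts), xtr0=p.b_bm(consts))
        np.testing.assert_allclose(initial_state(ct.get_model("M5"), full, consts),
                                   initial_state(ct.get_model("M3"), p, consts))


class TestVectorField:
    @pytest.mark.parametrize("name", ALL_MODELS)
    def test_fast_rhs_matches_reference(self, name, params, consts, pk, d135):
        """The integrator's specialised closure equals the reference RHS."""
        spec = ct.get_model(name)
        sol = PKSolution(pk, d135)
        fast = _make_fast_rhs(spec, params, consts, sol.central_amount)
        rng = np.random.default_rng(42)
        for _ in range(20):
            y = rng.uniform(0.01, 80.0, size=spec.n_tr + 2)
            t = rng.uniform(0.0, 8.0)
            np.testing.assert_allclose(
                np.asarray(fast(y, t)),
                rhs_pd(spec, params, consts, sol.central_amount(t), y),
                rtol=1e-12)

    def test_steady_state_derivatives_vanish(self, consts, pk):
        spec = ct.get_model("M2")
        p = ct.PDParameters(b=6.0, slope=1.0, k_tr=0.4, gamma=0.3)
        state = np.concatenate([[0.0, 0.0], initial_state(spec, p, consts)])
        dy = rhs(spec, p, consts, pk, ct.InfusionSchedule(()), 1.0, state)
        np.testing.assert_allclose(dy, 0.0, atol=1e-12)


class TestTrajectories:
    def test_drug_free_homeostasis_long_term(self, consts, pk):
        """100 drug-free days from the steady state: nothing moves."""
        for name in ("M2", "M5", "M11"):
            spec = ct.get_model(name)
            p = steady_state_params(
                ct.PDParameters(b=5.0, slope=4.0, k_tr=0.25, gamma=0.6), consts)
            grid = np.linspace(0.0, 100.0, 201)
            traj = ct.simulate_model(spec, p, consts, pk, ct.InfusionSchedule(()), grid)
            assert np.max(np.abs(traj.states - traj.states[0])) < 1e-6

    def test_drug_free_variant_equivalence(self, consts, pk):
        """Without drug, M5-M10 share one vector field, and so do M11/M12,
        even away from the steady state."""
        p = ct.PDParameters(b=5.0, slope=4.0, k_tr=0.25, gamma=0.6,
                            b0=3.5, xpr0=30.0, xtr0=55.0)
        grid = np.linspace(0.0, 60.0, 121)
        wbc = {name: ct.simulate_model(ct.get_model(name), p, consts, pk,
                                       ct.InfusionSchedule(()), grid).wbc
               for name in ALL_MODELS if ct.get_model(name).init == "I3"}
        for name in ("M6", "M7", "M8", "M9", "M10"):
            np.testing.assert_allclose(wbc[name], wbc["M5"], rtol=1e-7, atol=1e-9)
        np.testing.assert_allclose(wbc["M12"], wbc["M11"], rtol=1e-7, atol=1e-9)
        # the marrow-feedback pair genuinely differs off steady state
        assert np.max(np.abs(wbc["M11"] - wbc["M5"])) > 1e-3

    def test_suppression_rebound_overshoot(self, median_params, consts, pk, d135):
        """One high-dose cycle: dip below baseline, nadir, overshoot, return."""
        grid = np.arange(0.0, 150.0001, 0.1)
        traj = ct.simulate_model(ct.get_model("M5"), median_params, consts, pk,
                                 d135, grid)
        b = median_params.b
        assert traj.wbc.min() < 0.5 * b
        i_nadir = np.argmin(traj.wbc)
        assert traj.wbc[i_nadir:].max() > b  # feedback overshoot
        assert traj.wbc[-1] == pytest.approx(b, rel=0.02)  # back to baseline

    def test_nonnegative_under_heavy_dosing(self, consts, pk, dense_grid):
        p = steady_state_params(
            ct.PDParameters(b=5.0, slope=8.0, k_tr=0.2, gamma=0.8), consts)
        sched = ct.build_schedule("D123")
        traj = ct.simulate_model(ct.get_model("M10"), p, consts, pk, sched, dense_grid)
        assert np.all(traj.states >= 0.0)

    def test_matches_classic_friberg_implementation(self, consts, pk, d135):
        """Three-transit variant vs an independently coded textbook Friberg
        model (full coupled system, numerically integrated)."""
        p = ct.PDParameters(b=6.0, slope=2.0, k_tr=0.5, gamma=0.3)
        spec = ct.get_model("M2")
        grid = np.linspace(0.0, 30.0, 61)
        traj = ct.simulate_model(spec, p, consts, pk, d135, grid)

        k10, k12, k21 = (pk.k10 * HOURS_PER_DAY, pk.k12 * HOURS_PER_DAY,
                         pk.k21 * HOURS_PER_DAY)
        base = p.b * consts.k_ma / p.k_tr

        def friberg(t, x):
            x1, x2, prol, t1, t2, t3, circ = x
            rate = sum(e.rate for e in d135.events if e.start <= t < e.end)
            edrug = p.slope * math.log1p(consts.c_v * max(x1, 0.0))
            fb = (p.b / circ) ** p.gamma
            return [
                -(k10 + k12) * x1 + k21 * x2 + rate,
                k12 * x1 - k21 * x2,
                p.k_tr * prol * ((1 - edrug) * fb - 1),
                p.k_tr * (prol - t1),
                p.k_tr * (t1 - t2),
                p.k_tr * (t2 - t3),
                p.k_tr * t3 - consts.k_ma * circ,
            ]

        # integrate segment-by-segment so the dosing discontinuities never
        # fall inside a solver step
        breaks = sorted({0.0, 30.0} | {e.start for e in d135.events}
                        | {e.end for e in d135.events})
        x = np.array([0.0, 0.0, base, base, base, base, p.b])
        ref = {0.0: x[-1]}
        for a, b in zip(breaks[:-1], breaks[1:]):
            t_eval = grid[(grid > a) & (grid <= b)]
            seg = scipy.integrate.solve_ivp(
                friberg, (a, b), x, t_eval=np.unique(np.concatenate([t_eval, [b]])),
                rtol=1e-10, atol=1e-12, method="LSODA")
            assert seg.success
            x = seg.y[:, -1]
            for tt, val in zip(t_eval, seg.y[-1]):
                ref[tt] = val
        expected = np.array([ref[t] for t in grid])
        np.testing.assert_allclose(traj.wbc, expected, rtol=1e-5)

    def test_gamma_scaling_speeds_recovery_on_denser_schedule(
            self, median_params, consts, pk, dense_grid):
        """After high-dose exposure, the gamma-scaled variant recovers above
        1 G/L earlier than the reference model on the dense schedule."""
        sched = ct.build_schedule("D123")
        t5 = ct.recovery_stats(ct.simulate_model(
            ct.get_model("M5"), median_params, consts, pk, sched, dense_grid)).t_rec
        t10 = ct.recovery_stats(ct.simulate_model(
            ct.get_model("M10"), median_params, consts, pk, sched, dense_grid)).t_rec
        d135_sched = ct.build_schedule("D135")
        s5 = ct.recovery_stats(ct.simulate_model(
            ct.get_model("M5"), median_params, consts, pk, d135_sched, dense_grid)).t_rec
        s10 = ct.recovery_stats(ct.simulate_model(
            ct.get_model("M10"), median_params, consts, pk, d135_sched, dense_grid)).t_rec
        # the schedule contrast (D135 - D123) is far larger with gamma scaling
        assert (s10 - t10) > (s5 - t5)


class TestMaturationTime:
    def test_closed_forms(self):
        corrected, original = mean_maturation_time(1, 0.5)
        assert corrected == pytest.approx(48.0)
        assert original == pytest.approx(96.0)
        assert mean_maturation_time(3, 0.4)[0] == pytest.approx(3 / 0.4 * 24)

    def test_corrected_always_shorter(self):
        for n in (1, 3, 6):
            for k in (0.1, 0.5, 2.0):
                c, o = mean_maturation_time(n, k)
                assert c < o
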