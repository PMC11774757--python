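"""Newton solves, step control, events, restarts, scalar coupling."""

import numpy as np
import pytest

from mixdim import mesh as mk, presets
from mixdim.errors import NonlinearDivergenceError, StepFailureError
from mixdim.model import model_from_config
from mixdim.stepping import (BlockSystem, SolverSettings, adapt_dt, run)


def nonlinear_decay_model(n=2, with_source=True):
    mesh = mk.generate_slab(1, 1, 1, n)
    rate = "ksrc - Vmax*X/(Km+X)" if with_source else "-Vmax*X/(Km+X)"
    cfg = {
        "compartments": [{"name": "cytosol", "kind": "volume", "tag": 1}],
        "species": [{"name": "X", "compartment": "cytosol", "D": 1.0,
                     "initial": 5.0}],
        "parameters": [
            {"name": "ksrc", "value": 10.0, "unit": "uM/s"},
            {"name": "Vmax", "value": 50.0, "unit": "uM/s"},
            {"name": "Km", "value": 0.5, "unit": "uM"}],
        "reactions": [{"name": "mm", "type": "volume",
                       "compartment": "cytosol", "rate": rate,
                       "rate_unit": "uM/s", "stoichiometry": {"X": 1}}],
    }
    return model_from_config(cfg, mesh)


class TestNewton:
    def test_linear_model_single_iteration(self, ab_model):
        system = BlockSystem(ab_model, SolverSettings(dt=0.05))
        u0 = system.ops.initial_state()
        for guess in (u0, u0 + 3.0, np.zeros_like(u0)):
            _, iters = system.newton_solve(guess, u0, 0.05, 0.05)
            assert iters == 1

    def test_scalar_logistic_matches_root_oracle(self):
        """Implicit Euler update of du/dt = u(1-u) on one dof.

        Newton must land on the closed-form root of
        g(v) = (v - u0)/tau - v(1 - v), the same root a bisection oracle
        finds.
        """
        mesh = mk.generate_slab(1, 1, 1, 1)
        cfg = {
            "compartments": [{"name": "c", "kind": "volume", "tag": 1}],
            "species": [{"name": "u", "compartment": "c", "D": 0.0,
                         "initial": 0.2}],
            "parameters": [{"name": "r", "value": 1.0, "unit": "1/s"}],
            "reactions": [{"name": "lg", "type": "volume",
                           "compartment": "c", "rate": "r*u*(1 - u)",
                           "rate_unit": "uM/s", "stoichiometry": {"u": 1}}],
        }
        model = model_from_config(cfg, mesh)
        tau = 0.1
        system = BlockSystem(model, SolverSettings(dt=tau))
        u0 = system.ops.initial_state()
        u1, _ = system.newton_solve(u0, u0, tau, tau)
        # bisection oracle on the scalar implicit equation
        x0 = 0.2
        g = lambda v: (v - x0) / tau - v * (1 - v)
        lo, hi = x0, 1.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if g(lo) * g(mid) <= 0:
                hi = mid
            else:
                lo = mid
        assert np.allclose(u1, 0.5 * (lo + hi), atol=1e-9)

    def test_no_real_root_diverges(self):
        """du/dt = 1 + u^2 with a huge step has no implicit-Euler solution."""
        mesh = mk.generate_slab(1, 1, 1, 1)
        cfg = {
            "compartments": [{"name": "c", "kind": "volume", "tag": 1}],
            "species": [{"name": "u", "compartment": "c", "D": 0.0,
                         "initial": 0.0}],
            "parameters": [{"name": "a", "value": 1.0, "unit": "uM/s"}],
            "reactions": [{"name": "blow", "type": "volume",
                           "compartment": "c", "rate": "a*(1 + u*u)",
                           "rate_unit": "uM/s", "stoichiometry": {"u": 1}}],
        }
        model = model_from_config(cfg, mesh)
        system = BlockSystem(model, SolverSettings(dt=10.0))
        u0 = system.ops.initial_state()
        with pytest.raises(NonlinearDivergenceError):
            system.newton_solve(u0, u0, 10.0, 10.0)


class TestAdaptDt:
    s = SolverSettings(dt_min=1e-4, dt_max=1.0)

    @pytest.mark.parametrize("iters,factor", [(1, 1.25), (3, 1.25),
                                              (4, 1.0), (7, 1.0),
                                              (8, 0.7), (20, 0.7)])
    def test_policy(self, iters, factor):
        assert adapt_dt(iters, 0.1, self.s) == pytest.approx(0.1 * factor)

    def test_bounds(self):
        assert adapt_dt(1, 0.9, self.s) == 1.0
        assert adapt_dt(20, 1.2e-4, self.s) == 1e-4

    def test_monotone_in_iterations(self):
        taus = [adapt_dt(i, 0.1, self.s) for i in range(1, 15)]
        assert all(a >= b for a, b in zip(taus, taus[1:]))


class TestAdvance:
    def test_uniform_state_is_steady_without_reactions(self):
        mesh, cfg = presets.ab_volume()
        cfg["reactions"] = []
        model = model_from_config(cfg, mesh)
        series, _ = run(model, 0.5, SolverSettings(dt=0.1))
        assert np.allclose(series.states[-1], series.states[0], atol=1e-12)

    def test_closed_system_pointwise_conservation(self, ab_model):
        series, system = run(ab_model, 1.0, SolverSettings(dt=0.01),
                             output_times=[0.25, 0.5, 0.75, 1.0])
        for state in series.states:
            total = state[system.dofmap.of(ab_model, "A")] + \
                state[system.dofmap.of(ab_model, "B")]
            assert np.allclose(total, 2.5, rtol=1e-8)

    def test_adaptive_steps_respect_bounds(self):
        model = nonlinear_decay_model()
        s = SolverSettings(dt=1e-3, adaptive=True, dt_min=1e-4, dt_max=0.05)
        series, _ = run(model, 0.5, s)
        taus = [l["tau"] for l in series.step_log]
        assert max(taus) <= 0.05 + 1e-12
        assert min(taus) >= 1e-4 - 1e-15
        assert max(taus) > 1e-3     # growth actually happened

    def test_forced_restarts_reproduce_trajectory(self):
        """Tight Newton budgets force restarts; steady endpoints agree."""
        model = nonlinear_decay_model()
        base = dict(dt=0.02, newton_rtol=1e-6)
        sA, _ = run(model, 0.5, SolverSettings(**base))
        sB, _ = run(model, 0.5, SolverSettings(**base, max_newton=1))
        assert sum(l["restarts"] for l in sB.step_log) > 0
        assert sum(l["restarts"] for l in sA.step_log) == 0
        # both runs sit at the same steady state to within the shared
        # Newton tolerance (rtol 1e-6 here)
        assert np.abs(sA.states[-1] - sB.states[-1]).max() < 1e-5

    def test_restart_budget_exhaustion(self):
        mesh = mk.generate_slab(1, 1, 1, 1)
        cfg = {
            "compartments": [{"name": "c", "kind": "volume", "tag": 1}],
            "species": [{"name": "u", "compartment": "c", "D": 0.0,
                         "initial": 0.0}],
            "parameters": [{"name": "a", "value": 1e8, "unit": "uM/s"}],
            "reactions": [{"name": "blow", "type": "volume",
                           "compartment": "c", "rate": "a*(1 + u*u)",
                           "rate_unit": "uM/s", "stoichiometry": {"u": 1}}],
        }
        model = model_from_config(cfg, mesh)
        with pytest.raises(StepFailureError, match="restarts"):
            run(model, 1.0, SolverSettings(dt=1.0, max_restarts=3))


class TestEvents:
    def decay_with_event(self, condition, repeating=False):
        mesh = mk.generate_slab(1, 1, 1, 1)
        cfg = {
            "compartments": [{"name": "c", "kind": "volume", "tag": 1}],
            "species": [{"name": "X", "compartment": "c", "D": 0.0,
                         "initial": 1.0}],
            "parameters": [{"name": "kdec", "value": 2.0, "unit": "1/s"}],
            "reactions": [{"name": "dec", "type": "volume",
                           "compartment": "c", "rate": "kdec*X",
                           "rate_unit": "uM/s",
                           "stoichiometry": {"X": -1}}],
            "events": [{"name": "stop", "condition": condition,
                        "parameter": "kdec", "value": 0.0,
                        "repeating": repeating}],
        }
        return model_from_config(cfg, mesh)

    def test_time_trigger_freezes_flux(self):
        model = self.decay_with_event("t >= 0.5")
        series, system = run(model, 1.0, SolverSettings(dt=0.01),
                             output_times=[0.5, 1.0])
        assert system.params["kdec"] == 0.0
        # after the trigger the species stops decaying
        assert np.allclose(series.states[-1], series.states[-2], rtol=1e-12)

    def test_threshold_fires_at_analytic_crossing(self):
        """avg X = X0 e^{-k t} crosses 0.5 at t = ln 2 / k +- one step."""
        model = self.decay_with_event("avg_X <= 0.5")
        dt = 0.01
        series, system = run(model, 2.0, SolverSettings(dt=dt))
        assert system.params["kdec"] == 0.0
        final = float(series.states[-1][0])
        t_star = np.log(2.0) / 2.0
        # frozen value is the first discrete sample at or below threshold
        assert 0.5 * np.exp(-2 * dt) * 0.98 <= final <= 0.5
        crossing_steps = [l["t"] for l in series.step_log
                          if abs(l["t"] - t_star) <= dt]
        assert crossing_steps   # the trigger window covers the crossing

    def test_latching_fires_once(self):
        mesh = mk.generate_slab(1, 1, 1, 1)
        cfg = {
            "compartments": [{"name": "c", "kind": "volume", "tag": 1}],
            "species": [{"name": "X", "compartment": "c", "D": 0.0,
                         "initial": 1.0}],
            "parameters": [
                {"name": "amp", "value": 1.0, "unit": "uM/s"},
                {"name": "gain", "value": 1.0, "unit": "dimensionless"}],
            "reactions": [{"name": "osc", "type": "volume",
                           "compartment": "c",
                           "rate": "amp*gain*cos(6.283185307179586*t)",
                           "rate_unit": "uM/s", "stoichiometry": {"X": 1}}],
            # condition oscillates across the threshold; must fire once
            "events": [{"name": "dampen", "condition": "avg_X >= 1.05",
                        "parameter": "gain", "value": 0.5}],
        }
        model = model_from_config(cfg, mesh)
        series, system = run(model, 3.0, SolverSettings(dt=0.01))
        ev = system.events[0]
        assert ev.fired
        assert system.params["gain"] == 0.5

    def test_unknown_quantity_rejected(self):
        # event conditions are validated when the solver system is built
        model = self.decay_with_event("avg_Missing <= 0.5")
        with pytest.raises(Exception, match="unknown"):
            BlockSystem(model)
        BlockSystem(self.decay_with_event("t >= 1"))


class TestScalarCoupling:
    def build(self, **kw):
        mesh, cfg = presets.scalar_coupling_box(**kw)
        return model_from_config(cfg, mesh)

    def test_zero_rate_leaves_scalar_constant(self):
        model = self.build(k_rate=0.0, S0=1.7)
        series, _ = run(model, 0.2, SolverSettings(dt=0.01))
        assert series.scalars["S"] == 1.7

    def test_field_equal_scalar_is_identity(self):
        model = self.build(S0=2.0, field0=2.0)
        series, _ = run(model, 0.2, SolverSettings(dt=0.01))
        assert series.scalars["S"] == 2.0

    def test_relaxation_matches_predictor_corrector_closed_form(self):
        """Clamped field: per-step multiplier on (S - F) is 1 - c*tau*(1 - c*tau),

        which agrees with the implicit-Euler factor 1/(1 + c*tau) through
        second order in c*tau.
        """
        pref, k, rho = 1e-3, 1.0, 100.0
        model = self.build(S0=1.0, field0=2.0, k_rate=k, rho=rho,
                           prefactor=pref)
        tau = 0.01
        series, system = run(model, 0.1, SolverSettings(dt=tau))
        area = system.ops.lumped["om"].sum()
        c = pref * k * rho * area
        steps = len(series.step_log)
        factor = 1 - c * tau * (1 - c * tau)
        expected = 2.0 + (1.0 - 2.0) * factor ** steps
        assert series.scalars["S"] == pytest.approx(expected, rel=1e-13)
        implicit = 1 / (1 + c * tau)
        assert abs(factor - implicit) < (c * tau) ** 3
        # monotone exponential approach toward the clamped value
        assert 1.0 < series.scalars["S"] < 2.0


class TestSolverVariants:
    def test_gmres_matches_direct(self, binding_model):
        sA, _ = run(binding_model, 0.1, SolverSettings(dt=0.01))
        sB, _ = run(binding_model, 0.1,
                    SolverSettings(dt=0.01, linear_solver="gmres"))
        assert np.abs(sA.states[-1] - sB.states[-1]).max() < 1e-7

    def test_implicit_euler_first_order_on_scalar(self):
        """Fixed decay problem: error at t=1 halves with the step."""
        mesh = mk.generate_slab(1, 1, 1, 1)
        cfg = {
            "compartments": [{"name": "c", "kind": "volume", "tag": 1}],
            "species": [{"name": "u", "compartment": "c", "D": 0.0,
                         "initial": 1.0}],
            "parameters": [{"name": "k", "value": 1.0, "unit": "1/s"}],
            "reactions": [{"name": "dec", "type": "volume",
                           "compartment": "c", "rate": "k*u",
                           "rate_unit": "uM/s", "stoichiometry": {"u": -1}}],
        }
        model = model_from_config(cfg, mesh)
        errs = []
        for dt in (0.1, 0.05, 0.025):
            series, _ = run(model, 1.0, SolverSettings(dt=dt))
            errs.append(abs(float(series.states[-1][0]) - np.exp(-1.0)))
        orders = np.log(np.array(errs[:-1]) / errs[1:]) / np.log(2.0)
        assert np.all(np.abs(orders - 1.0) < 0.15)
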