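"""Monolithic implicit-Euler time integration.

Each step solves the fully coupled nonlinear system

    M (u^{n+1} - u^n) / tau_n + K u^{n+1} = b(u^{n+1}, t_{n+1})

by Newton-Raphson with the exact symbolic reaction Jacobian.  Around the
solve, a step performs: (i) prestep -- time-expression parameters are
evaluated at t_{n+1}, well-mixed scalar couplings apply their predictor
update, threshold events are checked; (ii) the Newton solve; (iii)
poststep -- the scalar-coupling corrector (consistent with the implicit
Euler discretization) and a negativity check.  On nonlinear divergence or
negative concentrations the step restarts with a reduced tau, up to a
restart budget.

The adaptive step policy grows tau by 1.25 when the previous step needed
at most 3 Newton iterations, shrinks it by 0.7 at 8 or more, and holds it
otherwise, clamped to [dt_min, dt_max]; these values are configurable.

For linear autonomous kinetics (constant reaction Jacobian) the assembled
Jacobian depends only on tau, and its sparse factorization is cached and
reused across steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield, asdict

import numpy as np
import scipy.sparse as sparse
import scipy.sparse.linalg as spla
import sympy as sp

from .errors import ModelError, NonlinearDivergenceError, StepFailureError
from .fem import DofMap, OperatorSet, ReactionAssembler
from .model import Model, _T

__all__ = [
    "SolverSettings", "EventSpec", "ScalarCouplingSpec", "BlockSystem",
    "SolutionSeries", "adapt_dt", "run",
]


@dataclass
class SolverSettings:
    """Tolerances and step-control knobs of the implicit-Euler solver."""

    dt: float = 0.01
    adaptive: bool = False
    dt_min: float = 1e-10
    dt_max: float = np.inf
    newton_atol: float = 1e-10
    newton_rtol: float = 1e-8
    max_newton: int = 25
    grow_factor: float = 1.25
    grow_threshold: int = 3
    shrink_factor: float = 0.7
    shrink_threshold: int = 8
    restart_factor: float = 0.5
    max_restarts: int = 10
    linear_solver: str = "direct"     # "direct" | "gmres"
    gmres_rtol: float = 1e-10
    # Restarting on negative concentrations is an optional mediation: P1
    # transport with a consistent mass matrix is not monotone, so sharp
    # fronts undershoot slightly at any step size; enable the restart only
    # for models where negativity signals a genuine step-size problem.
    negativity_restart: bool = False
    negativity_tol: float = 1e-8

    @classmethod
    def from_dict(cls, d: dict | None) -> "SolverSettings":
        return cls(**(d or {}))


def adapt_dt(iterations: int, tau: float, settings: SolverSettings) -> float:
    """Next time step from the previous step's Newton iteration count."""
    if iterations <= settings.grow_threshold:
        tau = tau * settings.grow_factor
    elif iterations >= settings.shrink_threshold:
        tau = tau * settings.shrink_factor
    return float(min(max(tau, settings.dt_min), settings.dt_max))


# ---------------------------------------------------------------------------
# events and scalar couplings


@dataclass
class EventSpec:
    """Threshold event: when ``condition`` holds at a prestep, assign
    ``value`` to ``parameter``; latching (fires once) unless repeating."""

    name: str
    condition: str
    parameter: str
    value: float
    repeating: bool = False


class _Event:
    def __init__(self, spec: EventSpec, model: Model):
        self.spec = spec
        if spec.parameter not in model.parameters:
            raise ModelError(
                f"event {spec.name!r} sets unknown parameter "
                f"{spec.parameter!r}")
        syms: dict[str, sp.Symbol] = {"t": _T}
        for n in model.parameters:
            syms[n] = model.symbols[n]
        self.avg_species = []
        for n in model.species:
            syms[f"avg_{n}"] = sp.Symbol(f"avg_{n}")
        try:
            expr = sp.sympify(spec.condition, locals=syms)
        except (sp.SympifyError, SyntaxError) as exc:
            raise ModelError(
                f"event {spec.name!r}: cannot parse condition: {exc}") \
                from None
        known = set(syms.values())
        unknown = expr.free_symbols - known
        if unknown:
            raise ModelError(
                f"event {spec.name!r}: condition references unknown "
                f"quantity {sorted(map(str, unknown))}")
        self.args = sorted((str(s) for s in expr.free_symbols))
        self.fn = sp.lambdify([sp.Symbol(a) if a != "t" else _T
                               for a in self.args], expr, "numpy")
        self.fired = False

    def check(self, t: float, params: dict[str, float],
              averages: dict[str, float]) -> bool:
        if self.fired and not self.spec.repeating:
            return False
        vals = []
        for a in self.args:
            if a == "t":
                vals.append(t)
            elif a.startswith("avg_") and a[4:] in averages:
                vals.append(averages[a[4:]])
            else:
                vals.append(params[a])
        return bool(self.fn(*vals))


@dataclass
class ScalarCouplingSpec:
    """A well-mixed scalar coupled to the PDE through a surface integral.

    The scalar S (exposed to rate laws as the prestep parameter
    ``parameter``) evolves as

        S(t+tau) = S(t) + tau * prefactor * int_Gamma k (F - S) dGamma

    where F is the trace of the volume species ``field`` on surface
    ``surface`` and k is ``rate_expression`` (parameters/constants only).
    Before the PDE solve the predictor uses F and S at t_n; after it, the
    corrector re-evaluates the integral with F at t_{n+1} and the
    predicted S, consistent with the implicit Euler discretization.
    """

    name: str
    parameter: str
    surface: str
    field: str
    rate_expression: str = "1.0"
    prefactor: float = 1.0


class _ScalarCoupling:
    def __init__(self, spec: ScalarCouplingSpec, model: Model,
                 dofmap: DofMap, ops: OperatorSet):
        self.spec = spec
        if spec.parameter not in model.parameters or \
                model.parameters[spec.parameter].kind != "prestep":
            raise ModelError(
                f"scalar coupling {spec.name!r} must drive a declared "
                "prestep parameter")
        comp = model.compartments.get(spec.surface)
        if comp is None or comp.kind != "surface":
            raise ModelError(
                f"scalar coupling {spec.name!r}: unknown surface "
                f"{spec.surface!r}")
        self.weights = ops.lumped[spec.surface]
        fcomp = model.species[spec.field].compartment
        if fcomp == spec.surface:
            start = dofmap.blocks[(spec.surface, spec.field)].start
            self.indices = np.arange(len(self.weights)) + start
        else:
            T = ops.traces[(spec.surface, fcomp)]
            cols = np.asarray(T.argmax(axis=1)).ravel()
            self.indices = cols + dofmap.blocks[(fcomp, spec.field)].start
        syms = {n: model.symbols[n] for n in model.parameters}
        expr = sp.sympify(spec.rate_expression, locals=syms)
        self.pnames = [n for n in model.parameters
                       if model.symbols[n] in expr.free_symbols]
        self.kfn = sp.lambdify([model.symbols[n] for n in self.pnames] + [_T],
                               expr, "numpy")
        self.value = model.parameters[spec.parameter].value

    def integral(self, state: np.ndarray, scalar: float, t: float,
                 params: dict[str, float]) -> float:
        k = self.kfn(*[params[n] for n in self.pnames], t)
        field = state[self.indices]
        return float(np.sum(self.weights * k * (field - scalar)))

    def predictor(self, state: np.ndarray, tau: float, t: float,
                  params: dict[str, float]) -> float:
        return self.value + tau * self.spec.prefactor * \
            self.integral(state, self.value, t, params)

    def corrector(self, state_new: np.ndarray, estimate: float, tau: float,
                  t_new: float, params: dict[str, float]) -> float:
        return self.value + tau * self.spec.prefactor * \
            self.integral(state_new, estimate, t_new, params)


# ---------------------------------------------------------------------------
# the assembled block system


class BlockSystem:
    """Operators, dof layout and solver state of one model instance."""

    def __init__(self, model: Model, settings: SolverSettings | None = None):
        self.model = model
        self.settings = settings or SolverSettings.from_dict(
            model.config_extras.get("solver"))
        self.dofmap = DofMap.build(model)
        self.ops = OperatorSet(model, self.dofmap)
        self.assembler = ReactionAssembler(model, self.dofmap, self.ops)
        self.params: dict[str, float] = {
            n: p.value for n, p in model.parameters.items()}
        self.events = [_Event(EventSpec(**e), model)
                       for e in model.config_extras.get("events", [])]
        self.couplings = [
            _ScalarCoupling(ScalarCouplingSpec(**c), model, self.dofmap,
                            self.ops)
            for c in model.config_extras.get("scalar_couplings", [])]
        self._lu_cache: dict[float, object] = {}
        self._const_jr = None
        # per-species scale for the negativity check
        self.scales = {}
        for n in model.species:
            vals = model.initial_values(n)
            self.scales[n] = max(float(np.max(np.abs(vals))), 1.0)

    # -- linear algebra -----------------------------------------------------

    def _reaction(self, u: np.ndarray, t: float):
        b, Jr = self.assembler.assemble(u, t, self.params)
        return b, Jr

    def _solve_linear(self, J: sparse.csr_matrix, rhs: np.ndarray,
                      tau: float) -> np.ndarray:
        if self.settings.linear_solver == "gmres":
            ilu = spla.spilu(J.tocsc(), drop_tol=1e-8, fill_factor=20)
            M = spla.LinearOperator(J.shape, ilu.solve)
            x, info = spla.gmres(J, rhs, M=M, rtol=self.settings.gmres_rtol,
                                 atol=0.0, maxiter=500)
            if info != 0:
                raise NonlinearDivergenceError(
                    f"Krylov solver failed (info={info})")
            return x
        if self.model.jacobian_constant:
            lu = self._lu_cache.get(tau)
            if lu is None:
                lu = spla.splu(J.tocsc())
                self._lu_cache[tau] = lu
            return lu.solve(rhs)
        return spla.splu(J.tocsc()).solve(rhs)

    def residual(self, u: np.ndarray, u_prev: np.ndarray, tau: float,
                 t: float) -> np.ndarray:
        b, _ = self._reaction(u, t)
        return self.ops.M @ (u - u_prev) / tau + self.ops.K @ u - b

    # -- Newton -------------------------------------------------------------

    def newton_solve(self, u_guess: np.ndarray, u_prev: np.ndarray,
                     tau: float, t_next: float):
        """Solve the implicit-Euler system at t_next; returns (u, iters)."""
        s = self.settings
        u = np.array(u_guess, dtype=float)
        if not np.all(np.isfinite(u)):
            raise NonlinearDivergenceError("non-finite initial guess")
        const = self.model.jacobian_constant
        need_jac = not const or self._const_jr is None
        b, Jr = self.assembler.assemble(u, t_next, self.params,
                                        jacobian=need_jac)
        if const:
            if self._const_jr is None:
                self._const_jr = Jr
            Jr = self._const_jr
        F = self.ops.M @ (u - u_prev) / tau + self.ops.K @ u - b
        norm0 = np.linalg.norm(F)
        tol = max(s.newton_atol, s.newton_rtol * norm0)
        if norm0 <= s.newton_atol:
            return u, 0
        for it in range(1, s.max_newton + 1):
            cached = const and s.linear_solver == "direct" and \
                tau in self._lu_cache
            if cached:
                du = self._lu_cache[tau].solve(-F)
            else:
                J = (self.ops.M / tau + self.ops.K - Jr).tocsr()
                du = self._solve_linear(J, -F, tau)
            u = u + du
            b, Jr_new = self.assembler.assemble(u, t_next, self.params,
                                                jacobian=not const)
            if not const:
                Jr = Jr_new
            F = self.ops.M @ (u - u_prev) / tau + self.ops.K @ u - b
            norm = np.linalg.norm(F)
            if not np.isfinite(norm):
                raise NonlinearDivergenceError(
                    f"residual became non-finite at iteration {it}")
            if norm <= tol:
                return u, it
            if norm > 1e6 * (norm0 + 1.0):
                raise NonlinearDivergenceError(
                    f"residual diverged at iteration {it} "
                    f"(|F|={norm:.3e})")
        raise NonlinearDivergenceError(
            f"no convergence in {s.max_newton} Newton iterations "
            f"(|F|={norm:.3e}, tol={tol:.3e})")

    # -- derived quantities ---------------------------------------------------

    def averages(self, state: np.ndarray) -> dict[str, float]:
        out = {}
        for (comp, sname), sl in self.dofmap.blocks.items():
            w = self.ops.lumped[comp]
            out[sname] = float(w @ state[sl] / w.sum())
        return out

    def _negativity_violation(self, state: np.ndarray):
        for (comp, sname), sl in self.dofmap.blocks.items():
            floor = -self.settings.negativity_tol * self.scales[sname]
            mn = float(state[sl].min())
            if mn < floor:
                return sname, mn
        return None

    # -- one step with restart mediation --------------------------------------

    def advance_step(self, state: np.ndarray, t: float, tau: float):
        """Advance one accepted step from t; returns (u_new, log_entry).

        Applies the prestep (events, scalar predictors), the Newton solve,
        and the poststep (scalar correctors, negativity check); on failure
        the step restarts with tau * restart_factor up to max_restarts.
        """
        s = self.settings
        restarts = 0
        failure = None
        while True:
            t_next = t + tau
            saved_params = dict(self.params)
            fired = []
            averages = self.averages(state)
            for ev in self.events:
                if ev.check(t_next, self.params, averages):
                    self.params[ev.spec.parameter] = ev.spec.value
                    fired.append(ev)
                    # a mutated parameter may sit inside cached Jacobians
                    self._lu_cache.clear()
                    self._const_jr = None
            estimates = {}
            for cp in self.couplings:
                est = cp.predictor(state, tau, t, self.params)
                estimates[cp.spec.name] = est
                self.params[cp.spec.parameter] = est
            try:
                u_new, iters = self.newton_solve(state, state, tau, t_next)
                neg = self._negativity_violation(u_new) \
                    if s.negativity_restart else None
                if neg is not None:
                    raise NonlinearDivergenceError(
                        f"negative concentration in {neg[0]!r} "
                        f"({neg[1]:.3e})")
            except NonlinearDivergenceError as exc:
                failure = exc
                self.params = saved_params
                restarts += 1
                if restarts > s.max_restarts:
                    raise StepFailureError(
                        f"step at t={t:.6g} failed after {s.max_restarts} "
                        f"restarts: {failure}") from None
                tau = max(tau * s.restart_factor, s.dt_min)
                continue
            for cp in self.couplings:
                new_val = cp.corrector(u_new, estimates[cp.spec.name], tau,
                                       t_next, self.params)
                cp.value = new_val
                self.params[cp.spec.parameter] = new_val
            for ev in fired:
                ev.fired = True
            log = {"t": t_next, "tau": tau, "newton_iterations": iters,
                   "restarts": restarts}
            return u_new, log


# ---------------------------------------------------------------------------
# full runs


@dataclass
class SolutionSeries:
    """Output times, nodal fields at outputs, and the per-step log."""

    model: Model
    dofmap: DofMap
    times: list[float] = dfield(default_factory=list)
    states: list[np.ndarray] = dfield(default_factory=list)
    step_log: list[dict] = dfield(default_factory=list)
    scalars: dict[str, float] = dfield(default_factory=dict)

    def field(self, species: str, index: int = -1) -> np.ndarray:
        return self.states[index][self.dofmap.of(self.model, species)]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.step_log)


def run(model: Model, t_final: float,
        settings: SolverSettings | dict | None = None,
        output_times=None, system: BlockSystem | None = None
        ) -> tuple[SolutionSeries, BlockSystem]:
    """Integrate the model to t_final; outputs at accepted steps.

    ``output_times``: requested output instants; each is reported at the
    nearest accepted step not exceeding it (no temporal interpolation).
    With ``output_times=None`` only initial and final states are stored.
    Returns the series and the block system (for post-processing).
    """
    if t_final <= 0:
        raise ModelError("t_final must be positive")
    if isinstance(settings, dict):
        settings = SolverSettings.from_dict(settings)
    if system is None:
        system = BlockSystem(model, settings)
    s = system.settings
    series = SolutionSeries(model, system.dofmap)
    u = system.ops.initial_state()
    t = 0.0
    series.times.append(0.0)
    series.states.append(u.copy())
    pending = sorted(float(x) for x in output_times) if output_times else []
    pending = [x for x in pending if x > 0]
    tau = s.dt
    prev_t, prev_u = 0.0, u.copy()
    eps = 1e-12 * max(t_final, 1.0)
    while t < t_final - eps:
        tau_eff = min(tau, t_final - t)
        u_new, log = system.advance_step(u, t, tau_eff)
        t_new = t + log["tau"]
        series.step_log.append(log)
        while pending and t_new > pending[0] + eps:
            series.times.append(prev_t)
            series.states.append(prev_u.copy())
            pending.pop(0)
        while pending and abs(t_new - pending[0]) <= eps:
            pending.pop(0)
            series.times.append(t_new)
            series.states.append(u_new.copy())
        prev_t, prev_u = t_new, u_new
        u, t = u_new, t_new
        if s.adaptive:
            tau = adapt_dt(log["newton_iterations"], log["tau"], system.settings)
        elif log["restarts"]:
            tau = s.dt          # uniform stepping resumes after a restart
    if not series.times or series.times[-1] != t:
        series.times.append(t)
        series.states.append(u.copy())
    series.scalars = {cp.spec.name: cp.value for cp in system.couplings}
    return series, system
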