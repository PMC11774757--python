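"""Verification machinery: analytic slab solution, L2 errors, convergence.

The reference problem is membrane phosphorylation in a slab: the
phosphorylated form u = [Ap] satisfies, at steady state,

    D u'' = k_p u             on (0, L),
    -D u'(0) = k_kin (A_tot - u(0))   (membrane flux at z = 0),
    u'(L) = 0                 (no flux at the far face),

because the conserved total A + Ap remains uniform at A_tot when both
forms share one diffusivity.  The closed-form solution is

    u(z) = C cosh((L - z)/lam),   lam = sqrt(D / k_p),
    C = k_kin A_tot / (sqrt(D k_p) sinh(L/lam) + k_kin cosh(L/lam)).

Convergence studies refine either the mesh (h) against this analytic
profile at steady state, or the time step (tau) against a fine-step
reference trajectory on a fixed mesh; both report least-squares fitted
orders.  A separate tau sweep against the analytic solution exposes the
error plateau where spatial resolution dominates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield

import numpy as np

from .errors import MixdimError
from .fem import simplex_quadrature
from .mesh import SubMeshView
from .model import Model, model_from_config, reduce_to_ode
from .presets import slab_phosphorylation
from .stepping import BlockSystem, SolverSettings, run

__all__ = [
    "SlabProblem", "ConvergenceReport", "analytic_slab", "l2_error",
    "solve_slab_steady", "convergence_study", "plateau_study",
    "plateau_onset", "ode_limit_check",
]


@dataclass
class SlabProblem:
    """Parameters of the slab phosphorylation problem (units: um, s, uM)."""

    L: float = 1.0
    D: float = 10.0
    k_kin: float = 50.0
    k_p: float = 10.0
    A_tot: float = 1.0

    def __post_init__(self):
        if min(self.L, self.D, self.k_p) <= 0 or self.k_kin < 0 \
                or self.A_tot < 0:
            raise ValueError("slab parameters must be positive")


def analytic_slab(problem: SlabProblem):
    """Closed-form steady profile of the phosphorylated form along z.

    Returns a vectorized function z -> u(z).  With k_kin = 0 the profile
    is identically zero (no phosphorylation source).
    """
    p = problem
    lam = math.sqrt(p.D / p.k_p)
    denom = math.sqrt(p.D * p.k_p) * math.sinh(p.L / lam) + \
        p.k_kin * math.cosh(p.L / lam)
    C = p.k_kin * p.A_tot / denom

    def profile(z):
        return C * np.cosh((p.L - np.asarray(z, dtype=float)) / lam)

    return profile


def l2_error(sub: SubMeshView, nodal: np.ndarray, exact, degree: int = 4
             ) -> float:
    """||u_h - u_e||_L2 over the submesh, by degree->=``degree`` quadrature.

    ``exact`` is called with an (n, d) coordinate array.  The quadrature is
    exact for polynomial integrands up to ``degree``, hence exact for the
    squared error of P1 fields against polynomial references of degree
    <= degree/2.
    """
    k = sub.entities.shape[1] - 1
    bary, w = simplex_quadrature(k, degree)
    coords = sub.coordinates[sub.entities]          # (ne, k+1, d)
    pts = np.einsum("qk,ekd->eqd", bary, coords)    # (ne, nq, d)
    vals = nodal[sub.entities]                      # (ne, k+1)
    uh = np.einsum("qk,ek->eq", bary, vals)
    ue = np.asarray(exact(pts.reshape(-1, pts.shape[-1]))).reshape(uh.shape)
    meas = sub.measures()
    # reference weights sum to 1/k!; physical scale is |K| * k!
    err2 = np.einsum("e,q,eq->", meas * math.factorial(k), w, (uh - ue) ** 2)
    return float(math.sqrt(max(err2, 0.0)))


# ---------------------------------------------------------------------------
# steady-state slab solves


def _slab_model(problem: SlabProblem, n: int) -> Model:
    mesh, config = slab_phosphorylation(D=problem.D, L=problem.L, n=n,
                                        k_kin=problem.k_kin,
                                        k_p=problem.k_p,
                                        A_tot=problem.A_tot)
    return model_from_config(config, mesh)


def solve_slab_steady(problem: SlabProblem, n: int,
                      rel_change_tol: float = 1e-10,
                      max_steps: int = 200) -> tuple[Model, BlockSystem,
                                                     np.ndarray]:
    """March implicit Euler to steady state on an n-per-edge slab mesh.

    Implicit Euler's steady states are independent of the step size, so
    large steps are taken; steadiness is declared when the relative L2
    change per unit time drops below ``rel_change_tol``.
    """
    model = _slab_model(problem, n)
    system = BlockSystem(model, SolverSettings(dt=1.0))
    u = system.ops.initial_state()
    M = system.ops.M
    t = 0.0
    # Implicit-Euler steady states do not depend on the step size, so march
    # with one large fixed tau: each step contracts the transient by
    # ~1/(1 + tau*k) and a constant tau lets factorizations be reused.
    tau = 1e4 / problem.k_p
    for _ in range(max_steps):
        u_new, log = system.advance_step(u, t, tau)
        t += log["tau"]
        du = u_new - u
        rel = math.sqrt(max(du @ (M @ du), 0.0)) / \
            max(math.sqrt(max(u_new @ (M @ u_new), 0.0)), 1e-300)
        u = u_new
        if rel / log["tau"] < rel_change_tol:
            return model, system, u
    raise MixdimError("steady state not reached within the step budget")


# ---------------------------------------------------------------------------
# convergence studies


@dataclass
class ConvergenceReport:
    """Refinement levels, L2 errors and fitted convergence orders."""

    mode: str                     # "h" | "tau"
    levels: list[float]           # h in um or tau in s, strictly decreasing
    errors: list[float]
    D: float
    pairwise_orders: list[float] = dfield(default_factory=list)
    fitted_order: float = float("nan")
    extra: dict = dfield(default_factory=dict)

    def finalize(self):
        lv, er = np.asarray(self.levels), np.asarray(self.errors)
        if np.any(er <= 0):
            raise MixdimError("non-positive error in convergence report")
        self.pairwise_orders = list(
            np.log(er[:-1] / er[1:]) / np.log(lv[:-1] / lv[1:]))
        slope = np.polyfit(np.log(lv), np.log(er), 1)[0]
        self.fitted_order = float(slope)
        return self


def convergence_study(problem: SlabProblem, mode: str, levels: int = 4,
                      base_n: int = 3, tau0: float = 0.02,
                      t_end: float = 0.2, mesh_n: int = 16,
                      ref_refine: int = 16) -> ConvergenceReport:
    """Mesh (mode="h") or time-step (mode="tau") refinement study.

    mode="h": meshes with n = base_n * 2^k cells per edge are solved to
    steady state and compared with the analytic profile; expected order 2.

    mode="tau": on a fixed mesh, uniform steps tau0 / 2^k to t_end are
    compared (in the discrete L2 norm) with a reference trajectory at
    1/``ref_refine`` of the finest step, isolating the O(tau) implicit
    Euler error from the spatial error; expected order 1.
    """
    if levels < 3:
        raise ValueError("need at least 3 refinement levels")
    if mode == "h":
        hs, errors = [], []
        for k in range(levels):
            n = base_n * 2 ** k
            model, system, u = solve_slab_steady(problem, n)
            sub = model.submeshes["cytosol"]
            exact = analytic_slab(problem)
            err = l2_error(sub, u[system.dofmap.of(model, "Ap")],
                           lambda pts: exact(pts[:, 2]))
            hs.append(problem.L / n)
            errors.append(err)
        return ConvergenceReport("h", hs, errors, problem.D).finalize()
    if mode == "tau":
        model = _slab_model(problem, mesh_n)
        system = BlockSystem(model, SolverSettings(dt=tau0))
        taus = [tau0 / 2 ** k for k in range(levels)]
        states = {}
        for tau in taus + [taus[-1] / ref_refine]:
            series, _ = run(model, t_end, SolverSettings(dt=tau))
            states[tau] = series.states[-1]
        ref = states[taus[-1] / ref_refine]
        M = system.ops.M
        errors = []
        for tau in taus:
            d = states[tau] - ref
            errors.append(math.sqrt(max(d @ (M @ d), 0.0)))
        return ConvergenceReport("tau", taus, errors,
                                 problem.D).finalize()
    raise ValueError("mode must be 'h' or 'tau'")


def plateau_study(problem: SlabProblem, taus, t_end: float = 3.0,
                  mesh_n: int = 8) -> ConvergenceReport:
    """Error versus the analytic steady profile at fixed t for a tau sweep.

    For large tau the implicit-Euler transient has not fully decayed and
    dominates; as tau shrinks the error flattens at the spatial floor of
    the fixed mesh (the plateau).  The critical tau at which the plateau
    sets in shrinks as D grows, because finer spatial floors demand more
    fully resolved transients.
    """
    model = _slab_model(problem, mesh_n)
    exact = analytic_slab(problem)
    sub = model.submeshes["cytosol"]
    errors = []
    taus = sorted((float(t) for t in taus), reverse=True)
    for tau in taus:
        series, system = run(model, t_end, SolverSettings(dt=tau))
        err = l2_error(sub, series.states[-1][series.dofmap.of(model, "Ap")],
                       lambda pts: exact(pts[:, 2]))
        errors.append(err)
    report = ConvergenceReport("tau", list(taus), errors, problem.D)
    # the plateau value is the error at the smallest tau (temporal error and
    # spatial error can partially cancel mid-sweep, dipping below it)
    report.extra["floor"] = errors[-1]
    return report.finalize()


def plateau_onset(taus, errors, factor: float = 2.0) -> float:
    """The tau at which the error curve meets ``factor`` x its floor.

    Levels must be sorted descending.  Log-log interpolation between the
    bracketing sweep points; returns the largest tau if the whole sweep is
    already on the plateau.
    """
    taus = np.asarray(taus, dtype=float)
    errors = np.asarray(errors, dtype=float)
    floor = errors[-1]
    target = factor * floor
    if errors[0] <= target:
        return float(taus[0])
    for i in range(len(taus) - 1):
        hi, lo = errors[i], errors[i + 1]
        if hi > target >= lo:
            f = (math.log(target) - math.log(lo)) / \
                (math.log(hi) - math.log(lo)) if hi > lo else 0.0
            return float(math.exp(
                math.log(taus[i + 1]) +
                f * (math.log(taus[i]) - math.log(taus[i + 1]))))
    return float(taus[-1])


# ---------------------------------------------------------------------------
# well-mixed (ODE) limit


def ode_limit_check(model: Model, D_large: float, t_final: float = 0.2,
                    dt: float = 2e-4, n_out: int = 20) -> float:
    """Max relative deviation of PDE compartment averages from the ODE.

    All volume diffusivities are set to ``D_large`` (surface species get a
    matching boost so nothing is artificially frozen), the PDE is run, and
    compartment averages are compared with the well-mixed reduction
    integrated by a high-order ODE solver.  The deviation for each species
    is normalized by the maximum magnitude of its ODE trajectory.
    """
    from scipy.integrate import solve_ivp

    from .model import build_containers, to_config, validate_model

    doc = to_config(model.containers)
    for s in doc["species"]:
        s["D"] = float(D_large)
    fast = validate_model(build_containers(doc), model.mesh,
                          model.axisymmetric, model.config_extras)
    out_times = list(np.linspace(0.0, t_final, n_out + 1)[1:])
    series, system = run(fast, t_final, SolverSettings(dt=dt),
                         output_times=out_times)
    ode = reduce_to_ode(fast)
    sol = solve_ivp(ode.rhs, (0.0, t_final), ode.y0, t_eval=series.times,
                    rtol=1e-10, atol=1e-12, method="LSODA")
    if not sol.success:
        raise MixdimError(f"ODE reference integration failed: {sol.message}")
    dev = 0.0
    for i, name in enumerate(ode.species):
        avg = np.array([system.averages(st)[name] for st in series.states])
        scale = max(np.max(np.abs(sol.y[i])), 1e-300)
        dev = max(dev, float(np.max(np.abs(avg - sol.y[i])) / scale))
    return dev
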