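"""P1 finite-element assembly on submesh views.

Volume and surface (Laplace-Beltrami) mass and stiffness matrices are built
by exact closed-form integration of products of linear barycentric basis
functions; gradients on surface triangles are computed in each triangle's
tangent plane, so surface diffusion needs no special casing.  Nonlinear
reaction terms use vertex (mass-lumped) quadrature, which keeps the
reaction Jacobian diagonal per vertex and exactly consistent with the
symbolic derivatives of the rate laws.

Sign convention for boundary reactions: a positive rate R on a surface
Gamma^q is a flux INTO the bordering volume (D grad(u) . n = -R with n the
outward normal); stoichiometric signs in the reaction specification select
direction per species.

Axisymmetric runs weight every volume and boundary integral by the radial
coordinate r (the first mesh coordinate); reported measures carry the 2*pi
factor at the post-processing layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sparse
from scipy.special import roots_jacobi

from .errors import EvaluationError, GeometryError, MeshConsistencyError, \
    ModelError
from .mesh import ParentMesh, SubMeshView, simplex_measures
from .model import Model, _COORDS, _T

import sympy as sp

__all__ = [
    "DofMap", "OperatorSet", "assemble_mass", "assemble_stiffness",
    "trace_operator", "assemble_reaction", "axisymmetric_weight",
    "simplex_quadrature", "lumped_mass",
]


# ---------------------------------------------------------------------------
# quadrature on the reference simplex (collapsed Gauss-Jacobi)


def simplex_quadrature(dim: int, degree: int):
    """Points (barycentric) and weights on the reference k-simplex.

    Returns ``(bary, w)`` with ``bary`` of shape (nq, k+1) and weights
    summing to the reference measure 1/k!.  Built by the Duffy collapse
    with Gauss-Jacobi weights, exact for total degree <= degree.
    """
    n = max(1, (degree + 2) // 2)
    if dim == 1:
        x, w = roots_jacobi(n, 0, 0)
        pts = (x[:, None] + 1) / 2
        wts = w / 2
        bary = np.column_stack([1 - pts[:, 0], pts[:, 0]])
        return bary, wts
    if dim == 2:
        xa, wa = roots_jacobi(n, 1, 0)
        xb, wb = roots_jacobi(n, 0, 0)
        a, b = (xa + 1) / 2, (xb + 1) / 2
        wa, wb = wa / 4, wb / 2      # includes the (1-x)^1 Jacobian factor
        A, B = np.meshgrid(a, b, indexing="ij")
        WA, WB = np.meshgrid(wa, wb, indexing="ij")
        x = A.ravel()
        y = (B * (1 - A)).ravel()
        w = (WA * WB).ravel()
        bary = np.column_stack([1 - x - y, x, y])
        return bary, w
    if dim == 3:
        xa, wa = roots_jacobi(n, 2, 0)
        xb, wb = roots_jacobi(n, 1, 0)
        xc, wc = roots_jacobi(n, 0, 0)
        a, b, c = (xa + 1) / 2, (xb + 1) / 2, (xc + 1) / 2
        wa, wb, wc = wa / 8, wb / 4, wc / 2
        A, B, C = np.meshgrid(a, b, c, indexing="ij")
        WA, WB, WC = np.meshgrid(wa, wb, wc, indexing="ij")
        x = A.ravel()
        y = (B * (1 - A)).ravel()
        z = (C * (1 - A) * (1 - B)).ravel()
        w = (WA * WB * WC).ravel()
        bary = np.column_stack([1 - x - y - z, x, y, z])
        return bary, w
    raise ValueError(f"unsupported simplex dimension {dim}")


# ---------------------------------------------------------------------------
# element matrices


def _gradients(coords: np.ndarray, entities: np.ndarray):
    """Per-element barycentric gradients and measures.

    ``coords``: (nv, d) vertex coordinates; ``entities``: (ne, k+1).
    Returns (grads, meas) with grads of shape (ne, k+1, d): the gradient of
    each basis function within the element's affine (tangent) plane.
    """
    pts = coords[entities]
    edges = pts[:, 1:, :] - pts[:, :1, :]          # (ne, k, d)
    gram = np.einsum("eki,eli->ekl", edges, edges)
    k = entities.shape[1] - 1
    det = np.linalg.det(gram)
    bad = np.nonzero(det <= 0)[0]
    if bad.size:
        raise GeometryError(f"degenerate entity {int(bad[0])} in assembly")
    meas = np.sqrt(det) / math.factorial(k)
    ginv = np.linalg.inv(gram)
    g_rest = np.einsum("ekl,eli->eki", ginv, edges)  # grads of lambda_1..k
    g0 = -g_rest.sum(axis=1, keepdims=True)
    grads = np.concatenate([g0, g_rest], axis=1)
    return grads, meas


def _resolve_weight(sub: SubMeshView, weight) -> np.ndarray | None:
    """Per-vertex weight values (linear interpolation is exact downstream)."""
    if weight is None:
        return None
    if callable(weight):
        vals = np.asarray(weight(sub.coordinates), dtype=float)
    else:
        vals = np.broadcast_to(np.asarray(weight, float),
                               (sub.num_vertices,)).astype(float)
    if vals.shape != (sub.num_vertices,):
        raise ModelError("weight must yield one value per vertex")
    return vals


def assemble_mass(sub: SubMeshView, weight=None) -> sparse.csr_matrix:
    """Consistent P1 mass matrix on a volume or surface submesh.

    Without a weight, entries come from the closed form
    int lambda_i lambda_j = |K| (1 + delta_ij) / ((k+1)(k+2)).  With a
    (vertex-interpolated) weight w, the exact formula for
    int w lambda_i lambda_j with P1 w is used, which is the declared
    quadrature for weighted (e.g. axisymmetric) integrals.
    """
    ents = sub.entities
    k = ents.shape[1] - 1
    meas = simplex_measures(sub.coordinates, ents)
    nloc = k + 1
    wvals = _resolve_weight(sub, weight)
    rows = np.repeat(ents, nloc, axis=1).ravel()
    cols = np.tile(ents, (1, nloc)).ravel()
    if wvals is None:
        base = (np.ones((nloc, nloc)) + np.eye(nloc)) / ((k + 1) * (k + 2))
        vals = (meas[:, None, None] * base[None, :, :]).ravel()
    else:
        # I3[i,j,l] = int lambda_i lambda_j lambda_l on the reference simplex
        # = k! a!b!c!/(k+3)! with multiplicities of (i,j,l)
        I3 = np.empty((nloc, nloc, nloc))
        fk = math.factorial(k) / math.factorial(k + 3)
        for i in range(nloc):
            for j in range(nloc):
                for l in range(nloc):
                    mult = [i, j, l]
                    prod = 1
                    for v in set(mult):
                        prod *= math.factorial(mult.count(v))
                    I3[i, j, l] = prod * fk
        we = wvals[ents]                                # (ne, nloc)
        local = np.einsum("el,ijl->eij", we, I3) * meas[:, None, None]
        vals = local.ravel()
    M = sparse.coo_matrix((vals, (rows, cols)),
                          shape=(sub.num_vertices, sub.num_vertices))
    return M.tocsr()


def lumped_mass(sub: SubMeshView, weight=None) -> np.ndarray:
    """Diagonal (row-sum lumped) mass vector; strictly positive for P1."""
    M = assemble_mass(sub, weight)
    return np.asarray(M.sum(axis=1)).ravel()


def assemble_stiffness(sub: SubMeshView, D=1.0, weight=None
                       ) -> sparse.csr_matrix:
    """P1 stiffness matrix scaled by the diffusivity D.

    ``D`` may be a constant or a callable of the vertex coordinates; for
    surface submeshes the gradients live in each triangle's tangent plane,
    yielding the Laplace-Beltrami operator.  An optional weight (for
    axisymmetric integrals) multiplies the integrand, elementwise averaged
    (exact for P1 weights).
    """
    ents = sub.entities
    grads, meas = _gradients(sub.coordinates, ents)
    if callable(D):
        dvals = np.asarray(D(sub.coordinates), dtype=float)
        if np.any(dvals < 0):
            raise ModelError("negative diffusivity sampled")
        dcell = dvals[ents].mean(axis=1)
    else:
        if D < 0:
            raise ModelError("negative diffusivity")
        dcell = np.full(len(ents), float(D))
    wvals = _resolve_weight(sub, weight)
    if wvals is not None:
        dcell = dcell * wvals[ents].mean(axis=1)
    local = np.einsum("eki,eli->ekl", grads, grads) * \
        (meas * dcell)[:, None, None]
    nloc = ents.shape[1]
    rows = np.repeat(ents, nloc, axis=1).ravel()
    cols = np.tile(ents, (1, nloc)).ravel()
    K = sparse.coo_matrix((local.ravel(), (rows, cols)),
                          shape=(sub.num_vertices, sub.num_vertices))
    return K.tocsr()


def trace_operator(volume: SubMeshView, surface: SubMeshView
                   ) -> sparse.csr_matrix:
    """Boolean injection matrix T with (T u_volume) = u at surface vertices."""
    vol_map = volume.parent_to_local()
    rows, cols = [], []
    for s_local, p in enumerate(surface.vertex_parent):
        v_local = vol_map.get(int(p))
        if v_local is None:
            raise MeshConsistencyError(
                f"surface vertex (parent {int(p)}) is absent from the "
                "bordering volume submesh")
        rows.append(s_local)
        cols.append(v_local)
    T = sparse.coo_matrix((np.ones(len(rows)), (rows, cols)),
                          shape=(surface.num_vertices, volume.num_vertices))
    return T.tocsr()


def axisymmetric_weight(mesh: ParentMesh):
    """The weight w(r, z) = r applied to all integrals of a 2D (r,z) mesh."""
    if mesh.dim != 2:
        raise ModelError("axisymmetric weighting applies to 2D meshes")
    if mesh.vertices[:, 0].min() < -1e-12 * max(mesh.bbox_scale, 1.0):
        raise GeometryError("axisymmetric mesh has vertices with r < 0")

    def weight(coords: np.ndarray) -> np.ndarray:
        return np.maximum(coords[:, 0], 0.0)

    return weight


# ---------------------------------------------------------------------------
# degree-of-freedom layout


@dataclass
class DofMap:
    """Contiguous block of dofs per (compartment, species) in declaration order."""

    blocks: dict[tuple[str, str], slice]
    sizes: dict[tuple[str, str], int]
    total: int

    @classmethod
    def build(cls, model: Model) -> "DofMap":
        blocks, sizes = {}, {}
        offset = 0
        for comp_name, sname in model.block_order:
            n = model.submeshes[comp_name].num_vertices
            blocks[(comp_name, sname)] = slice(offset, offset + n)
            sizes[(comp_name, sname)] = n
            offset += n
        return cls(blocks, sizes, offset)

    def of(self, model: Model, species: str) -> slice:
        comp = model.species[species].compartment
        return self.blocks[(comp, species)]


class OperatorSet:
    """All constant sparse operators of a model on its dof layout.

    Holds, per species, the compartment mass and diffusivity-scaled
    stiffness; per surface compartment, the lumped surface mass and the
    trace operators from each bordering volume; and the global block mass /
    stiffness matrices used by the implicit Euler residual.
    """

    def __init__(self, model: Model, dofmap: DofMap):
        self.model = model
        self.dofmap = dofmap
        weight = axisymmetric_weight(model.mesh) if model.axisymmetric \
            else None
        self.weight = weight
        self.mass: dict[str, sparse.csr_matrix] = {}
        self.stiffness: dict[str, sparse.csr_matrix] = {}
        self.lumped: dict[str, np.ndarray] = {}     # per compartment
        self.traces: dict[tuple[str, str], sparse.csr_matrix] = {}
        comp_mass: dict[str, sparse.csr_matrix] = {}
        for comp in model.compartments.values():
            sub = model.submeshes[comp.name]
            comp_mass[comp.name] = assemble_mass(sub, weight)
            self.lumped[comp.name] = lumped_mass(sub, weight)
            if comp.kind == "surface":
                for vol_name in dict.fromkeys(comp.borders):
                    self.traces[(comp.name, vol_name)] = trace_operator(
                        model.submeshes[vol_name], sub)
        self.comp_mass = comp_mass
        for s in model.species.values():
            sub = model.submeshes[s.compartment]
            self.mass[s.name] = comp_mass[s.compartment]
            self.stiffness[s.name] = assemble_stiffness(sub, s.D, weight)
        # global block-diagonal transport operators
        order = [sname for _, sname in model.block_order]
        self.M = sparse.block_diag([self.mass[s] for s in order],
                                   format="csr")
        self.K = sparse.block_diag([self.stiffness[s] for s in order],
                                   format="csr")

    def initial_state(self) -> np.ndarray:
        u = np.empty(self.dofmap.total)
        for (comp, sname), sl in self.dofmap.blocks.items():
            u[sl] = self.model.initial_values(sname)
        return u


# ---------------------------------------------------------------------------
# nonlinear reaction assembly (vertex quadrature)


class ReactionAssembler:
    """Evaluates reaction load vectors and Jacobian blocks at a state.

    Each compiled reaction is turned into: the set of vertices it acts on
    (compartment vertices for volume reactions, surface vertices
    otherwise), gather indices from the global vector for every symbol in
    its rate law, lumped quadrature weights, and per-species scatter
    indices with unit-conversion coefficients.
    """

    def __init__(self, model: Model, dofmap: DofMap, operators: OperatorSet):
        self.model = model
        self.dofmap = dofmap
        self.ops = operators
        self.terms = []
        for cr in model.compiled.values():
            self.terms.append(self._prepare(cr))

    # -- preparation --------------------------------------------------------

    def _prepare(self, cr):
        model = self.model
        r = cr.spec
        comp = model.compartments[r.compartment]
        if comp.kind == "volume":
            sub = model.submeshes[comp.name]
            nloc = sub.num_vertices
            coords = sub.coordinates
            weights = self.ops.lumped[comp.name]
            gather = {n: np.arange(nloc) +
                      self.dofmap.blocks[(comp.name, n)].start
                      for n in cr.rate_species}
            scatter = {}
            for n, st in r.stoichiometry.items():
                scatter[n] = (np.arange(nloc) +
                              self.dofmap.blocks[(comp.name, n)].start,
                              st * cr.volume_factor, None)
        else:
            sub = model.submeshes[comp.name]
            nloc = sub.num_vertices
            coords = sub.coordinates
            weights = self.ops.lumped[comp.name]
            gather = {}
            for n in set(cr.rate_species) | set(r.stoichiometry):
                scomp = model.species[n].compartment
                if scomp == comp.name:
                    idx = np.arange(nloc) + \
                        self.dofmap.blocks[(comp.name, n)].start
                else:
                    T = self.ops.traces[(comp.name, scomp)]
                    # rows are surface-local; T is boolean so the gathered
                    # index is just the column of the single unit entry
                    cols = np.asarray(T.argmax(axis=1)).ravel()
                    idx = cols + self.dofmap.blocks[(scomp, n)].start
                if n in cr.rate_species:
                    gather[n] = idx
            scatter = {}
            for n, st in r.stoichiometry.items():
                scomp = model.species[n].compartment
                if scomp == comp.name:
                    idx = np.arange(nloc) + \
                        self.dofmap.blocks[(comp.name, n)].start
                    factor = st * cr.surface_factor
                else:
                    T = self.ops.traces[(comp.name, scomp)]
                    cols = np.asarray(T.argmax(axis=1)).ravel()
                    idx = cols + self.dofmap.blocks[(scomp, n)].start
                    factor = st * cr.volume_factor
                scatter[n] = (idx, factor, None)
        # lambdified rate and derivatives: args are rate species arrays,
        # then parameter symbols, then t, then coordinates
        pnames = [n for n in model.parameters
                  if model.symbols[n] in cr.expr.free_symbols or
                  any(model.symbols[n] in d.free_symbols
                      for d in cr.derivs.values())]
        args = [model.symbols[n] for n in cr.rate_species] + \
               [model.symbols[n] for n in pnames] + \
               [_T] + list(_COORDS[:model.mesh.dim])
        rate_fn = sp.lambdify(args, cr.expr, "numpy")
        deriv_fns = {n: sp.lambdify(args, d, "numpy")
                     for n, d in cr.derivs.items()}
        return {
            "cr": cr, "nloc": nloc, "coords": coords, "weights": weights,
            "gather": gather, "scatter": scatter, "pnames": pnames,
            "rate_fn": rate_fn, "deriv_fns": deriv_fns,
        }

    # -- evaluation ---------------------------------------------------------

    def _param_values(self, term, t: float, params: dict[str, float]):
        """Parameter argument arrays at time t (space params at vertices)."""
        model = self.model
        out = []
        for n in term["pnames"]:
            p = model.parameters[n]
            if p.kind == "space":
                expr = sp.sympify(p.expression)
                fn = sp.lambdify(list(_COORDS[:model.mesh.dim]), expr,
                                 "numpy")
                out.append(np.broadcast_to(
                    np.asarray(fn(*term["coords"].T), float),
                    (term["nloc"],)))
            elif p.kind == "time":
                expr = sp.sympify(p.expression).subs(
                    {model.symbols[q]: params.get(q,
                                                  model.parameters[q].value)
                     for q in model.parameters
                     if model.parameters[q].kind == "prestep"})
                out.append(float(sp.lambdify(_T, expr, "numpy")(t)))
            else:
                out.append(params.get(n, p.value))
        return out

    def assemble(self, state: np.ndarray, t: float,
                 params: dict[str, float] | None = None,
                 jacobian: bool = True):
        """Load vector b and reaction Jacobian at (state, t).

        Returns ``(b, J)`` where the implicit-Euler residual is
        M (u - u_prev)/tau + K u - b and the full Jacobian is
        M/tau + K - J.  With ``jacobian=False`` only b is assembled and J
        is None (used when a cached constant Jacobian is in play).
        """
        params = params or {}
        N = self.dofmap.total
        b = np.zeros(N)
        rows, cols, vals = [], [], []
        for term in self.terms:
            cr = term["cr"]
            xargs = [state[term["gather"][n]] for n in cr.rate_species]
            pargs = self._param_values(term, t, params)
            cargs = list(term["coords"].T)
            rate = np.broadcast_to(
                np.asarray(term["rate_fn"](*xargs, *pargs, t, *cargs),
                           float), (term["nloc"],))
            if not np.all(np.isfinite(rate)):
                loc = int(np.nonzero(~np.isfinite(rate))[0][0])
                raise EvaluationError(
                    f"reaction {cr.spec.name!r} evaluated non-finite at "
                    f"vertex {loc} (coords "
                    f"{term['coords'][loc]})")
            wq = term["weights"]
            dcache = {}
            if jacobian:
                for m, dfn in term["deriv_fns"].items():
                    dcache[m] = np.broadcast_to(
                        np.asarray(dfn(*xargs, *pargs, t, *cargs), float),
                        (term["nloc"],))
            for n, (idx, factor, _) in term["scatter"].items():
                np.add.at(b, idx, factor * wq * rate)
                for m, dvals in dcache.items():
                    rows.append(idx)
                    cols.append(term["gather"][m])
                    vals.append(factor * wq * dvals)
        if not jacobian:
            return b, None
        if rows:
            J = sparse.coo_matrix(
                (np.concatenate(vals),
                 (np.concatenate(rows), np.concatenate(cols))),
                shape=(N, N)).tocsr()
        else:
            J = sparse.csr_matrix((N, N))
        return b, J


def assemble_reaction(model: Model, state: np.ndarray, t: float,
                      dofmap: DofMap | None = None,
                      operators: OperatorSet | None = None,
                      params: dict[str, float] | None = None):
    """One-shot reaction assembly (residual loads + Jacobian blocks)."""
    if not np.all(np.isfinite(state)):
        raise EvaluationError("non-finite state passed to assembly")
    dofmap = dofmap or DofMap.build(model)
    operators = operators or OperatorSet(model, dofmap)
    return ReactionAssembler(model, dofmap, operators).assemble(
        state, t, params)
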