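"""P1 assembly: mass, stiffness, traces, reaction terms, axisymmetry."""

import math

import numpy as np
import pytest
import scipy.sparse as sparse
import sympy as sp

from mixdim import fem, mesh as mk
from mixdim.fem import DofMap, OperatorSet, ReactionAssembler, \
    assemble_mass, assemble_stiffness, axisymmetric_weight, lumped_mass, \
    simplex_quadrature, trace_operator
from mixdim.model import model_from_config
from mixdim import presets


class TestQuadrature:
    @pytest.mark.parametrize("dim,exponents", [
        (1, (3,)), (2, (2, 2)), (2, (4, 0)), (3, (2, 1, 1)), (3, (0, 0, 4)),
    ])
    def test_exact_on_monomials(self, dim, exponents):
        """Quadrature integrates reference-simplex monomials exactly.

        Oracle: int x1^a x2^b ... = a! b! ... / (a+b+...+dim)! on the unit
        simplex (Dirichlet integral formula).
        """
        bary, w = simplex_quadrature(dim, sum(exponents))
        pts = bary[:, 1:]                      # cartesian reference coords
        vals = np.prod(pts ** np.asarray(exponents), axis=1)
        got = float(np.sum(w * vals))
        exact = np.prod([math.factorial(a) for a in exponents]) / \
            math.factorial(sum(exponents) + dim)
        assert got == pytest.approx(exact, rel=1e-13)

    @pytest.mark.parametrize("dim", [1, 2, 3])
    def test_weights_sum_to_reference_measure(self, dim):
        _, w = simplex_quadrature(dim, 3)
        assert w.sum() == pytest.approx(1 / math.factorial(dim), rel=1e-13)


class TestMass:
    def test_unit_tet_entries(self, unit_tet_mesh):
        sub = mk.extract_submesh(unit_tet_mesh, 1, 3)
        M = assemble_mass(sub).toarray()
        assert np.allclose(np.diag(M), 1 / 60)
        off = M[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1 / 120)

    def test_surface_triangle_entries(self, unit_tet_mesh):
        sub = mk.extract_submesh(unit_tet_mesh, 5, 2)   # slanted face
        A = sub.measure()
        M = assemble_mass(sub).toarray()
        assert np.allclose(np.diag(M), A / 6)
        assert np.allclose(M[~np.eye(3, dtype=bool)], A / 12)

    @pytest.mark.parametrize("builder,tag,dim,measure", [
        (lambda: mk.generate_slab(1, 1, 5, 2), 1, 3, 5.0),
        (lambda: mk.generate_slab(1, 1, 5, 2), 2, 2, 1.0),
        (lambda: mk.generate_nested(2, 1, 0.4, 2), 1, 2, None),
    ])
    def test_partition_of_unity(self, builder, tag, dim, measure):
        mesh = builder()
        sub = mk.extract_submesh(mesh, tag, dim)
        M = assemble_mass(sub)
        expect = measure if measure is not None else sub.measure()
        assert M.sum() == pytest.approx(expect, rel=1e-12)
        assert np.allclose(lumped_mass(sub), np.asarray(M.sum(axis=1)).ravel())

    def test_spd(self, slab_mesh, rng):
        sub = mk.extract_submesh(slab_mesh, 1, 3)
        M = assemble_mass(sub)
        assert (abs(M - M.T) > 1e-15).nnz == 0
        for _ in range(3):
            v = rng.standard_normal(sub.num_vertices)
            assert v @ (M @ v) > 0


class TestStiffness:
    def test_constant_in_null_space(self, slab_mesh):
        sub = mk.extract_submesh(slab_mesh, 1, 3)
        K = assemble_stiffness(sub, 3.0)
        c = np.full(sub.num_vertices, 2.7)
        norm = sparse.linalg.norm(K)
        assert np.abs(K @ c).max() <= 1e-12 * norm

    def test_dirichlet_energy_of_linear_function(self):
        mesh = mk.generate_rectangle(1.0, 1.0, 5)
        sub = mk.extract_submesh(mesh, 1, 2)
        D = 4.2
        K = assemble_stiffness(sub, D)
        u = sub.coordinates[:, 0]
        assert u @ (K @ u) == pytest.approx(D, rel=1e-12)

    def test_laplace_beltrami_sphere_energy(self):
        """Surface Dirichlet energy of u = z on the unit sphere -> 8*pi/3.

        Inscribed triangulations underestimate; the deficit must shrink
        with refinement.
        """
        target = 8 * np.pi / 3
        vals = []
        for h in (0.7, 0.35):
            mesh = mk.generate_nested(2.0, 1.0, h, dim=3)
            sub = mk.extract_submesh(mesh, 4, 2)
            K = fem.assemble_stiffness(sub, 1.0)
            u = sub.coordinates[:, 2]
            vals.append(u @ (K @ u))
        assert abs(vals[1] - target) < abs(vals[0] - target)
        assert vals[1] == pytest.approx(target, rel=0.05)

    def test_negative_diffusivity_rejected(self, slab_mesh):
        sub = mk.extract_submesh(slab_mesh, 1, 3)
        with pytest.raises(Exception, match="negative"):
            assemble_stiffness(sub, -1.0)


class TestTrace:
    def test_constant_passes_through(self, slab_mesh):
        vol = mk.extract_submesh(slab_mesh, 1, 3)
        surf = mk.extract_submesh(slab_mesh, 2, 2)
        T = trace_operator(vol, surf)
        assert np.allclose(T @ np.ones(vol.num_vertices), 1.0)
        assert np.allclose(np.asarray(T.sum(axis=1)).ravel(), 1.0)

    def test_two_sided_traces_agree(self, nested_disk_mesh):
        surf = mk.extract_submesh(nested_disk_mesh, 4, 1)
        f = lambda c: 1.0 + 2 * c[:, 0] - c[:, 1]
        traces = []
        for tag in (1, 2):
            vol = mk.extract_submesh(nested_disk_mesh, tag, 2)
            T = trace_operator(vol, surf)
            traces.append(T @ f(vol.coordinates))
        assert np.allclose(traces[0], traces[1], atol=1e-13)

    def test_boundary_mass_reproduces_boundary_integral(self, slab_mesh):
        """u^T (T^T Ms T) u = int_membrane u^2 for linear u (exact)."""
        vol = mk.extract_submesh(slab_mesh, 1, 3)
        surf = mk.extract_submesh(slab_mesh, 2, 2)
        T = trace_operator(vol, surf)
        Ms = assemble_mass(surf)
        u = vol.coordinates[:, 0]          # u = x; int_{z=0} x^2 = 1/3
        val = u @ (T.T @ (Ms @ (T @ u)))
        assert val == pytest.approx(1 / 3, rel=1e-12)

    def test_missing_vertex_raises(self, nested_disk_mesh):
        core = mk.extract_submesh(nested_disk_mesh, 2, 2)
        pm = mk.extract_submesh(nested_disk_mesh, 3, 1)  # exterior surface
        with pytest.raises(Exception, match="absent"):
            trace_operator(core, pm)


class TestReactionAssembly:
    def _system(self, model):
        dofmap = DofMap.build(model)
        ops = OperatorSet(model, dofmap)
        return dofmap, ops, ReactionAssembler(model, dofmap, ops)

    def test_zero_rate_zero_blocks(self):
        mesh, cfg = presets.ab_volume()
        cfg["reactions"][0]["rate"] = "0*A"
        model = model_from_config(cfg, mesh)
        _, ops, asm = self._system(model)
        b, J = asm.assemble(ops.initial_state(), 0.0)
        assert np.allclose(b, 0.0)
        assert J.nnz == 0 or np.allclose(J.toarray(), 0.0)

    def test_vsv_antisymmetric_loads(self, transport_model):
        """Transport across an interior surface moves what it takes.

        After unit conversion the molecule flux into the receiving volume
        equals the flux out of the donor: the summed load vanishes.
        """
        from mixdim.units import MOLECULES_PER_UM3
        model = transport_model
        dofmap, ops, asm = self._system(model)
        state = ops.initial_state()
        rng = np.random.default_rng(7)
        state += rng.uniform(0, 0.3, size=state.shape)
        b, _ = asm.assemble(state, 0.0)
        out_total = b[dofmap.of(model, "u_out")].sum()
        in_total = b[dofmap.of(model, "u_in")].sum()
        assert out_total == pytest.approx(-in_total, rel=1e-12)

    @pytest.mark.parametrize("fixture", ["slab", "binding", "transport",
                                         "nonlinear"])
    def test_jacobian_matches_finite_difference(self, fixture, rng):
        if fixture == "slab":
            mesh, cfg = presets.slab_phosphorylation(n=2)
        elif fixture == "binding":
            mesh, cfg = presets.volume_surface_binding(n=2)
        elif fixture == "transport":
            mesh, cfg = presets.nested_transport(h=0.6)
        else:
            mesh, cfg = presets.slab_phosphorylation(n=2)
            cfg["reactions"][1]["rate"] = "kp*Ap*Ap/(1 + Ap)"
        model = model_from_config(cfg, mesh)
        dofmap, ops, asm = self._system(model)
        state = ops.initial_state() + rng.uniform(0.1, 1.0,
                                                  size=dofmap.total)
        b0, J = asm.assemble(state, 0.0)
        J = J.toarray()
        h = 1e-6
        cols = rng.choice(dofmap.total, size=min(20, dofmap.total),
                          replace=False)
        for j in cols:
            e = np.zeros(dofmap.total)
            e[j] = h
            bp, _ = asm.assemble(state + e, 0.0, jacobian=False)
            bm, _ = asm.assemble(state - e, 0.0, jacobian=False)
            fd = (bp - bm) / (2 * h)
            scale = max(np.abs(J[:, j]).max(), 1.0)
            assert np.allclose(J[:, j], fd, atol=1e-5 * scale)

    def test_deterministic_assembly(self, binding_model):
        dofmap, ops, asm = self._system(binding_model)
        state = ops.initial_state() + 0.1
        b1, J1 = asm.assemble(state, 0.0)
        b2, J2 = asm.assemble(state, 0.0)
        assert np.array_equal(b1, b2)
        assert (J1 != J2).nnz == 0

    def test_nonfinite_rate_names_reaction(self):
        mesh, cfg = presets.ab_volume()
        cfg["reactions"][0]["rate"] = "kf/(A - 2.0)"   # IC has A = 2
        model = model_from_config(cfg, mesh)
        dofmap, ops, asm = self._system(model)
        with pytest.raises(Exception, match="interconvert"):
            asm.assemble(ops.initial_state(), 0.0)


class TestAxisymmetric:
    def test_weighted_measure_is_half_r2h(self):
        mesh = mk.generate_rectangle(2.0, 3.0, 8)
        sub = mk.extract_submesh(mesh, 1, 2)
        w = axisymmetric_weight(mesh)
        M = assemble_mass(sub, w)
        # int r dr dz over [0,R]x[0,H] = R^2 H / 2
        assert M.sum() == pytest.approx(2.0 ** 2 * 3.0 / 2, rel=1e-12)

    def test_weighted_lumped_consistent(self):
        mesh = mk.generate_rectangle(1.0, 1.0, 6)
        sub = mk.extract_submesh(mesh, 1, 2)
        w = axisymmetric_weight(mesh)
        M = assemble_mass(sub, w)
        assert np.allclose(lumped_mass(sub, w),
                           np.asarray(M.sum(axis=1)).ravel())

    def test_radial_diffusion_matches_radial_oracle(self):
        """Axisymmetric 2D run agrees with an independent 1D radial solve.

        Pure diffusion of u0(r) = r^2 in a cylinder of radius 1 (no-flux
        walls); the oracle is a finite-difference Crank-Nicolson solve of
        u_t = D (1/r) (r u_r)_r on a fine radial grid.
        """
        D, T = 1.0, 0.02
        mesh = mk.generate_rectangle(1.0, 0.2, 16, 4)
        cfg = {
            "axisymmetric": True,
            "compartments": [{"name": "c", "kind": "volume", "tag": 1}],
            "species": [{"name": "u", "compartment": "c", "D": D,
                         "initial": "x*x"}],
            "parameters": [], "reactions": [],
        }
        model = model_from_config(cfg, mesh)
        from mixdim.stepping import SolverSettings, run
        series, system = run(model, T, SolverSettings(dt=T / 200))
        # radial FD oracle
        N = 800
        r = np.linspace(0, 1, N + 1)
        hr = 1 / N
        u = r ** 2
        rf = (r[:-1] + r[1:]) / 2          # face radii
        dt = T / 4000
        main = np.zeros(N + 1)
        lower = np.zeros(N)
        upper = np.zeros(N)
        rc = np.where(r == 0, hr / 8, r)   # control-volume radius weights
        vol = np.where((r > 0) & (r < 1), r * hr, np.where(
            r == 0, hr ** 2 / 8, r[-1] * hr / 2))
        for i in range(N + 1):
            wl = rf[i - 1] / hr if i > 0 else 0.0
            wr = rf[i] / hr if i < N else 0.0
            main[i] = (wl + wr) * D / vol[i]
            if i > 0:
                lower[i - 1] = -wl * D / vol[i]
            if i < N:
                upper[i] = -wr * D / vol[i]
        A = sparse.diags([lower, main, upper], [-1, 0, 1]).tocsc()
        I = sparse.identity(N + 1, format="csc")
        lhs = sparse.linalg.splu((I + dt / 2 * A).tocsc())
        for _ in range(4000):
            u = lhs.solve((I - dt / 2 * A) @ u)
        rv = system.model.submeshes["c"].coordinates[:, 0]
        fem_u = series.states[-1]
        oracle_u = np.interp(rv, r, u)
        assert np.abs(fem_u - oracle_u).max() < 5e-3

    def test_negative_radius_rejected(self):
        mesh = mk.generate_rectangle(1.0, 1.0, 3)
        shifted = mk.ParentMesh(mesh.vertices - [0.5, 0.0], mesh.cells,
                                mesh.facets, mesh.cell_tags, mesh.facet_tags)
        with pytest.raises(Exception, match="r < 0"):
            axisymmetric_weight(shifted)


class TestConservationCoupling:
    def test_volume_surface_transport_conserves_molecules(self):
        """Discrete coupling conserves mass: d/dt (volume + surface) = 0."""
        from mixdim.postprocess import total_amount
        from mixdim.stepping import SolverSettings, run
        mesh, cfg = presets.volume_surface_binding(n=3)
        model = model_from_config(cfg, mesh)
        series, system = run(model, 0.5, SolverSettings(dt=0.005))
        totals = [total_amount(system, st, ["C", "S"])
                  for st in series.states]
        drift = (max(totals) - min(totals)) / totals[0]
        assert drift < 1e-10
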