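"""Ready-made model configurations used by the verification suite and docs.

Each builder returns ``(mesh, config)``; pass them through
:func:`mixdim.model.model_from_config` to get a runnable model.  Parameter
defaults are the reference conditions of the shipped verification
problems; geometry sizes are in um, rates in the package's base units.
"""

from __future__ import annotations

from .mesh import ParentMesh, generate_nested, generate_slab

__all__ = [
    "slab_phosphorylation", "ab_volume", "volume_surface_binding",
    "nested_transport", "scalar_coupling_box",
]


def slab_phosphorylation(D: float = 10.0, L: float = 1.0, n: int = 8,
                         k_kin: float = 50.0, k_p: float = 10.0,
                         A_tot: float = 1.0) -> tuple[ParentMesh, dict]:
    """Membrane phosphorylation / bulk dephosphorylation in a slab.

    A protein A is phosphorylated at the z=0 membrane with first-order
    surface rate k_kin (um/s) acting on its membrane trace, and the
    phosphorylated form Ap is dephosphorylated throughout the volume at
    rate k_p (1/s).  Both forms share the diffusivity D, so A + Ap stays
    uniform at A_tot and the steady state has the closed form implemented
    in :mod:`mixdim.verify`.  With no-flux side walls the solution is
    one-dimensional along the slab thickness.
    """
    mesh = generate_slab(L, L, L, n)
    config = {
        "compartments": [
            {"name": "cytosol", "kind": "volume", "tag": 1},
            {"name": "membrane", "kind": "surface", "tag": 2,
             "borders": ["cytosol"]},
        ],
        "species": [
            {"name": "A", "compartment": "cytosol", "D": D,
             "initial": A_tot, "unit": "uM"},
            {"name": "Ap", "compartment": "cytosol", "D": D,
             "initial": 0.0, "unit": "uM"},
        ],
        "parameters": [
            {"name": "kkin", "value": k_kin, "unit": "um/s"},
            {"name": "kp", "value": k_p, "unit": "1/s"},
        ],
        "reactions": [
            {"name": "phosphorylation", "type": "volume-surface",
             "compartment": "membrane", "rate": "kkin*A",
             "rate_unit": "uM*um/s",
             "stoichiometry": {"A": -1, "Ap": 1}},
            {"name": "dephosphorylation", "type": "volume",
             "compartment": "cytosol", "rate": "kp*Ap",
             "rate_unit": "uM/s",
             "stoichiometry": {"Ap": -1, "A": 1}},
        ],
    }
    return mesh, config


def ab_volume(kf: float = 2.0, kr: float = 1.0, D: float = 1.0,
              A0: float = 2.0, B0: float = 0.5, n: int = 2,
              L: float = 1.0) -> tuple[ParentMesh, dict]:
    """Closed A <-> B interconversion in one volume (mass conserving)."""
    mesh = generate_slab(L, L, L, n)
    config = {
        "compartments": [{"name": "cytosol", "kind": "volume", "tag": 1}],
        "species": [
            {"name": "A", "compartment": "cytosol", "D": D, "initial": A0},
            {"name": "B", "compartment": "cytosol", "D": D, "initial": B0},
        ],
        "parameters": [
            {"name": "kf", "value": kf, "unit": "1/s"},
            {"name": "kr", "value": kr, "unit": "1/s"},
        ],
        "reactions": [
            {"name": "interconvert", "type": "volume",
             "compartment": "cytosol", "rate": "kf*A - kr*B",
             "rate_unit": "uM/s", "stoichiometry": {"A": -1, "B": 1}},
        ],
    }
    return mesh, config


def volume_surface_binding(D: float = 10.0, k_on: float = 5.0,
                           k_off: float = 1.0, C0: float = 1.0,
                           S0: float = 0.0, n: int = 4,
                           L: float = 1.0) -> tuple[ParentMesh, dict]:
    """Reversible binding of a volume species C to membrane sites S.

    The membrane rate k_on*C - k_off*S is a flux out of the volume and
    into the surface pool; total molecules (volume + surface) are
    conserved.  k_on is in um/s; k_off converts surface density back to a
    volume-side flux (uM*um**3/(molecule*s)).
    """
    mesh = generate_slab(L, L, L, n)
    config = {
        "compartments": [
            {"name": "cytosol", "kind": "volume", "tag": 1},
            {"name": "membrane", "kind": "surface", "tag": 2,
             "borders": ["cytosol"]},
        ],
        "species": [
            {"name": "C", "compartment": "cytosol", "D": D, "initial": C0},
            {"name": "S", "compartment": "membrane", "D": 0.1,
             "initial": S0, "unit": "molecule/um**2"},
        ],
        "parameters": [
            {"name": "kon", "value": k_on, "unit": "um/s"},
            {"name": "koff", "value": k_off,
             "unit": "uM*um**3/(molecule*s)"},
        ],
        "reactions": [
            {"name": "binding", "type": "volume-surface",
             "compartment": "membrane", "rate": "kon*C - koff*S",
             "rate_unit": "uM*um/s", "stoichiometry": {"C": -1, "S": 1}},
        ],
    }
    return mesh, config


def nested_transport(k: float = 2.0, D: float = 10.0, u_out0: float = 1.0,
                     u_in0: float = 0.0, h: float = 0.4,
                     outer: float = 2.0, inner: float = 1.0,
                     dim: int = 2) -> tuple[ParentMesh, dict]:
    """Passive transport across an organelle membrane (volume-surface-volume).

    Nested disk (or ball) with a shell species u_out and a core species
    u_in exchanged across the interface at rate k*(u_out - u_in), the
    simplest pump-free membrane transport.
    """
    mesh = generate_nested(outer, inner, h, dim=dim)
    config = {
        "compartments": [
            {"name": "cytosol", "kind": "volume", "tag": 1},
            {"name": "organelle", "kind": "volume", "tag": 2},
            {"name": "om", "kind": "surface", "tag": 4,
             "borders": ["cytosol", "organelle"]},
        ],
        "species": [
            {"name": "u_out", "compartment": "cytosol", "D": D,
             "initial": u_out0},
            {"name": "u_in", "compartment": "organelle", "D": D,
             "initial": u_in0},
        ],
        "parameters": [{"name": "k", "value": k, "unit": "um/s"}],
        "reactions": [
            {"name": "transport", "type": "volume-surface-volume",
             "compartment": "om", "rate": "k*(u_out - u_in)",
             "rate_unit": "uM*um/s",
             "stoichiometry": {"u_out": -1, "u_in": 1}},
        ],
    }
    return mesh, config


def scalar_coupling_box(k_rate: float = 1.0, rho: float = 100.0,
                        prefactor: float = 1.0e-3, S0: float = 1.0,
                        field0: float = 2.0, D: float = 100.0,
                        n: int = 2, L: float = 1.0
                        ) -> tuple[ParentMesh, dict]:
    """A well-mixed exterior scalar coupled to a boxed volume species.

    Mirrors the treatment of a cytosolic concentration outside the meshed
    domain: the scalar S (a prestep parameter) relaxes toward the membrane
    trace of the interior field through

        S(t+tau) = S(t) + tau * prefactor * int_Gamma k_rate*rho*(F - S) dG

    applied as an explicit predictor before each PDE solve and an
    implicit-Euler-consistent corrector after it.  With no reactions the
    interior field stays clamped at its initial value, which isolates the
    coupling scheme itself.
    """
    mesh = generate_slab(L, L, L, n)
    config = {
        "compartments": [
            {"name": "interior", "kind": "volume", "tag": 1},
            {"name": "om", "kind": "surface", "tag": 2,
             "borders": ["interior"]},
        ],
        "species": [
            {"name": "F", "compartment": "interior", "D": D,
             "initial": field0},
        ],
        "parameters": [
            {"name": "kv", "value": k_rate, "unit": "um/s"},
            {"name": "rho", "value": rho, "unit": "molecule/um**2"},
            {"name": "S", "kind": "prestep", "value": S0, "unit": "uM"},
        ],
        "reactions": [],
        "scalar_couplings": [
            {"name": "S", "parameter": "S", "surface": "om", "field": "F",
             "rate_expression": "kv*rho", "prefactor": prefactor},
        ],
    }
    return mesh, config
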