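"""Declarative model layer: species, compartments, reactions, parameters.

A model is described by four containers (insertion-ordered, which fixes the
global degree-of-freedom ordering downstream), bound to a tagged parent
mesh by :func:`validate_model`.  Rate laws are strings over declared
symbols, parsed with sympy so that exact species-Jacobians are available to
the nonlinear solver.

Unit conventions (see :mod:`mixdim.units`): volume concentrations in uM,
surface concentrations in molecule/um^2, diffusivities in um^2/s.  Volume
reaction rates must carry the dimension of uM/s; surface-bound reaction
rates the dimension of uM*um/s (equivalently molecule/(um^2*s), the two
being related by the fixed Avogadro factor).  A positive boundary rate is a
flux *into* the volume compartment (along the inward normal).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dfield

import numpy as np
import sympy as sp

from . import units
from .errors import ModelError, SchemaError, UnitError
from .mesh import ParentMesh, SubMeshView, SurfaceAdjacency, extract_submesh, \
    surface_adjacency

__all__ = [
    "CompartmentSpec", "SpeciesSpec", "ParameterSpec", "ReactionSpec",
    "Containers", "Model", "build_containers", "load_config", "to_config",
    "parse_rate", "validate_model", "reduce_by_conservation", "reduce_to_ode",
]

_RESERVED = {"t", "x", "y", "z"}

_COORDS = sp.symbols("x y z")
_T = sp.Symbol("t")

#: functions admitted inside rate expressions (all smooth)
_FUNMAP = {
    "exp": sp.exp, "log": sp.log, "tanh": sp.tanh, "sqrt": sp.sqrt,
    "cos": sp.cos, "sin": sp.sin, "cosh": sp.cosh, "sinh": sp.sinh,
    "pow": sp.Pow,
    # smooth minimum and Hill activation, provided so that models never need
    # hard conditionals inside rates (discontinuities belong in events)
    "softmin": lambda a, b, k=20: -sp.log(sp.exp(-k * a) + sp.exp(-k * b)) / k,
    "hill": lambda c, K, n: c ** n / (K ** n + c ** n),
}

_BANNED_FUNCS = (sp.Piecewise, sp.sign, sp.Abs, sp.Max, sp.Min,
                 sp.floor, sp.ceiling, sp.Heaviside)


# ---------------------------------------------------------------------------
# specification records


@dataclass
class CompartmentSpec:
    name: str
    kind: str                      # "volume" | "surface"
    tag: int
    borders: list[str] = dfield(default_factory=list)  # surfaces: 1 or 2 names


@dataclass
class SpeciesSpec:
    name: str
    compartment: str
    D: float                       # um^2/s
    initial: float | str = 0.0     # constant or expression in x, y, z
    unit: str = ""                 # default: uM (volume) / molecule/um**2 (surface)


@dataclass
class ParameterSpec:
    name: str
    kind: str = "constant"         # constant | time | space | prestep
    value: float = 0.0
    expression: str = ""
    unit: str = "dimensionless"


@dataclass
class ReactionSpec:
    name: str
    type: str        # volume | surface | volume-surface | volume-surface-volume
    compartment: str               # binding compartment (volume or surface name)
    rate: str                      # symbolic rate law
    stoichiometry: dict[str, float]
    rate_unit: str = ""


@dataclass
class Containers:
    compartments: dict[str, CompartmentSpec]
    species: dict[str, SpeciesSpec]
    parameters: dict[str, ParameterSpec]
    reactions: dict[str, ReactionSpec]


# ---------------------------------------------------------------------------
# configuration documents

_COMP_KEYS = {"name", "kind", "tag", "borders"}
_SPEC_KEYS = {"name", "compartment", "D", "initial", "unit"}
_PARAM_KEYS = {"name", "kind", "value", "expression", "unit"}
_RXN_KEYS = {"name", "type", "compartment", "rate", "stoichiometry",
             "rate_unit"}
_RXN_TYPES = {"volume", "surface", "volume-surface", "volume-surface-volume"}
_PARAM_KINDS = {"constant", "time", "space", "prestep"}


def load_config(source) -> dict:
    """Load a model configuration from a YAML/JSON path, text or dict."""
    if isinstance(source, dict):
        return source
    import yaml
    text = source
    if "\n" not in str(source):
        try:
            with open(source) as fh:
                text = fh.read()
        except OSError as exc:
            raise SchemaError(f"cannot read configuration {source}: {exc}") \
                from None
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise SchemaError("configuration root must be a mapping")
    return doc


def _check_entry(entry: dict, allowed: set, required: set, path: str):
    if not isinstance(entry, dict):
        raise SchemaError(f"{path}: expected a mapping")
    unknown = set(entry) - allowed
    if unknown:
        raise SchemaError(f"{path}: unknown keys {sorted(unknown)}")
    missing = required - set(entry)
    if missing:
        raise SchemaError(f"{path}: missing required keys {sorted(missing)}")


def build_containers(config: dict) -> Containers:
    """Populate the four containers from a configuration document.

    Insertion order of each array is preserved; it determines the global
    block ordering of the assembled system.
    """
    config = load_config(config)
    comps: dict[str, CompartmentSpec] = {}
    for i, entry in enumerate(config.get("compartments", [])):
        path = f"compartments[{i}]"
        _check_entry(entry, _COMP_KEYS, {"name", "kind", "tag"}, path)
        if entry["kind"] not in ("volume", "surface"):
            raise SchemaError(f"{path}: kind must be volume or surface")
        if entry["name"] in comps:
            raise SchemaError(f"{path}: duplicate compartment {entry['name']!r}")
        comps[entry["name"]] = CompartmentSpec(
            entry["name"], entry["kind"], int(entry["tag"]),
            list(entry.get("borders", [])))
    species: dict[str, SpeciesSpec] = {}
    for i, entry in enumerate(config.get("species", [])):
        path = f"species[{i}]"
        _check_entry(entry, _SPEC_KEYS, {"name", "compartment", "D"}, path)
        name = entry["name"]
        if name in species:
            raise SchemaError(f"{path}: duplicate species {name!r}")
        if name in _RESERVED:
            raise SchemaError(f"{path}: {name!r} is a reserved symbol")
        species[name] = SpeciesSpec(name, entry["compartment"],
                                    float(entry["D"]),
                                    entry.get("initial", 0.0),
                                    entry.get("unit", ""))
    params: dict[str, ParameterSpec] = {}
    for i, entry in enumerate(config.get("parameters", [])):
        path = f"parameters[{i}]"
        _check_entry(entry, _PARAM_KEYS, {"name"}, path)
        name = entry["name"]
        if name in params or name in species:
            raise SchemaError(f"{path}: duplicate symbol {name!r}")
        if name in _RESERVED:
            raise SchemaError(f"{path}: {name!r} is a reserved symbol")
        kind = entry.get("kind", "constant")
        if kind not in _PARAM_KINDS:
            raise SchemaError(f"{path}: unknown parameter kind {kind!r}")
        params[name] = ParameterSpec(name, kind,
                                     float(entry.get("value", 0.0)),
                                     str(entry.get("expression", "")),
                                     entry.get("unit", "dimensionless"))
    reactions: dict[str, ReactionSpec] = {}
    for i, entry in enumerate(config.get("reactions", [])):
        path = f"reactions[{i}]"
        _check_entry(entry, _RXN_KEYS,
                     {"name", "type", "compartment", "rate", "stoichiometry"},
                     path)
        name = entry["name"]
        if name in reactions:
            raise SchemaError(f"{path}: duplicate reaction {name!r}")
        if entry["type"] not in _RXN_TYPES:
            raise SchemaError(f"{path}: unknown reaction type {entry['type']!r}")
        stoich = {k: float(v) for k, v in entry["stoichiometry"].items()}
        for sname in stoich:
            if sname not in species:
                raise SchemaError(f"{path}: undeclared species {sname!r} "
                                  "in stoichiometry")
        reactions[name] = ReactionSpec(name, entry["type"],
                                       entry["compartment"], entry["rate"],
                                       stoich, entry.get("rate_unit", ""))
    return Containers(comps, species, params, reactions)


def to_config(containers: Containers) -> dict:
    """Round-trip write: containers back to a configuration document."""
    doc: dict = {"compartments": [], "species": [], "parameters": [],
                 "reactions": []}
    for c in containers.compartments.values():
        e = {"name": c.name, "kind": c.kind, "tag": c.tag}
        if c.borders:
            e["borders"] = list(c.borders)
        doc["compartments"].append(e)
    for s in containers.species.values():
        e = {"name": s.name, "compartment": s.compartment, "D": s.D,
             "initial": s.initial}
        if s.unit:
            e["unit"] = s.unit
        doc["species"].append(e)
    for p in containers.parameters.values():
        e = {"name": p.name, "kind": p.kind, "unit": p.unit}
        if p.expression:
            e["expression"] = p.expression
        else:
            e["value"] = p.value
        doc["parameters"].append(e)
    for r in containers.reactions.values():
        e = {"name": r.name, "type": r.type, "compartment": r.compartment,
             "rate": r.rate, "stoichiometry": dict(r.stoichiometry)}
        if r.rate_unit:
            e["rate_unit"] = r.rate_unit
        doc["reactions"].append(e)
    return doc


# ---------------------------------------------------------------------------
# symbolic rates


def parse_rate(expression: str, symbols: dict[str, sp.Symbol],
               species_symbols: set[str] | None = None) -> sp.Expr:
    """Parse a rate-law string into a differentiable sympy expression.

    ``symbols`` maps every admissible name (species, parameters) to its
    symbol; ``t, x, y, z`` are always available.  Only the whitelisted
    smooth functions are allowed, and the result must be differentiable in
    every referenced species symbol -- hard conditionals are rejected with a
    pointer to the event mechanism.
    """
    from sympy.parsing.sympy_parser import parse_expr

    local = {**_FUNMAP, **symbols,
             "t": _T, "x": _COORDS[0], "y": _COORDS[1], "z": _COORDS[2],
             # parse non-smooth constructs to their real sympy forms so the
             # ban below can reject them with a useful message
             "Max": sp.Max, "Min": sp.Min, "Abs": sp.Abs, "abs": sp.Abs,
             "sign": sp.sign, "floor": sp.floor, "ceiling": sp.ceiling,
             "Piecewise": sp.Piecewise, "Heaviside": sp.Heaviside}
    try:
        # restricted namespace: unknown names become bare symbols caught
        # below instead of colliding with sympy builtins (Q, N, S, ...)
        expr = parse_expr(str(expression), local_dict=local,
                          global_dict={"Symbol": sp.Symbol,
                                       "Float": sp.Float,
                                       "Integer": sp.Integer,
                                       "Rational": sp.Rational,
                                       "Function": sp.Function},
                          evaluate=True)
    except (sp.SympifyError, SyntaxError, TypeError) as exc:
        raise ModelError(f"cannot parse rate {expression!r}: {exc}") from None
    if not isinstance(expr, sp.Basic):
        raise ModelError(f"rate {expression!r} is not a scalar expression")
    known = set(symbols.values()) | {_T, *_COORDS}
    unknown = expr.free_symbols - known
    if unknown:
        raise ModelError(
            f"rate {expression!r} references unknown symbol(s) "
            f"{sorted(str(s) for s in unknown)}")
    if expr.has(*_BANNED_FUNCS):
        raise ModelError(
            f"rate {expression!r} contains a non-smooth construct; "
            "express discontinuities as events instead")
    if species_symbols:
        for name in species_symbols:
            s = symbols[name]
            if s in expr.free_symbols:
                d = sp.diff(expr, s)
                if d.has(sp.Derivative):
                    raise ModelError(
                        f"rate {expression!r} is not differentiable in {name}")
    return expr


# ---------------------------------------------------------------------------
# the validated model


@dataclass
class CompiledReaction:
    """A reaction with its symbolic rate, derivatives and unit conversions.

    ``volume_factor`` converts the declared rate unit to uM/s (volume
    reactions) or uM*um/s (surface-bound); ``surface_factor`` to
    molecule/(um^2*s).  Stoichiometric signs are applied at assembly.
    """

    spec: ReactionSpec
    expr: sp.Expr
    derivs: dict[str, sp.Expr]
    species: list[str]             # species with nonzero stoichiometry
    rate_species: list[str]        # species appearing in the rate law
    volume_factor: float
    surface_factor: float
    surface: str | None            # binding surface name, if surface-bound


class Model:
    """Validated binding of the containers to a parent mesh.

    Attributes of interest after construction:

    - ``submeshes``: compartment name -> :class:`SubMeshView`
    - ``adjacency``: surface compartment name -> :class:`SurfaceAdjacency`
    - ``compiled``: reaction name -> :class:`CompiledReaction`
    - ``symbols``: name -> sympy symbol for every species and parameter
    - ``reduction``: list of (eliminated species, reconstruction expression)
    - ``jacobian_constant``: True when every species-derivative of every
      rate is state- and time-independent (linear autonomous kinetics),
      which lets the time stepper reuse matrix factorizations.
    """

    def __init__(self, containers: Containers, mesh: ParentMesh,
                 axisymmetric: bool = False, config_extras: dict | None = None):
        self.containers = containers
        self.mesh = mesh
        self.axisymmetric = bool(axisymmetric)
        self.config_extras = dict(config_extras or {})
        self.reduction: list[tuple[str, sp.Expr, dict]] = []
        self._validate()

    # convenience accessors -------------------------------------------------

    @property
    def compartments(self):
        return self.containers.compartments

    @property
    def species(self):
        return self.containers.species

    @property
    def parameters(self):
        return self.containers.parameters

    @property
    def reactions(self):
        return self.containers.reactions

    def species_of(self, comp: str) -> list[str]:
        return [s.name for s in self.species.values() if s.compartment == comp]

    def species_unit(self, name: str) -> str:
        sp_ = self.species[name]
        if sp_.unit:
            return sp_.unit
        kind = self.compartments[sp_.compartment].kind
        return "uM" if kind == "volume" else "molecule/um**2"

    # validation ------------------------------------------------------------

    def _validate(self):
        c = self.containers
        if self.axisymmetric:
            if self.mesh.dim != 2:
                raise ModelError("axisymmetric models require a 2D (r,z) mesh")
            if self.mesh.vertices[:, 0].min() < -1e-12 * self.mesh.bbox_scale:
                raise ModelError("axisymmetric mesh has vertices with r < 0")
        self.symbols: dict[str, sp.Symbol] = {}
        for name in list(c.species) + list(c.parameters):
            self.symbols[name] = sp.Symbol(name)
        self.submeshes: dict[str, SubMeshView] = {}
        self.adjacency: dict[str, SurfaceAdjacency] = {}
        for comp in c.compartments.values():
            dim = self.mesh.dim if comp.kind == "volume" else self.mesh.dim - 1
            try:
                self.submeshes[comp.name] = extract_submesh(
                    self.mesh, comp.tag, dim)
            except ModelError as exc:
                raise ModelError(
                    f"compartment {comp.name!r}: {exc}") from None
            if comp.kind == "surface":
                adj = surface_adjacency(self.mesh, comp.tag)
                if not 1 <= len(comp.borders) <= 2:
                    raise ModelError(
                        f"surface {comp.name!r} must list 1 or 2 bordering "
                        "volume compartments")
                declared_tags = []
                for bname in comp.borders:
                    b = c.compartments.get(bname)
                    if b is None or b.kind != "volume":
                        raise ModelError(
                            f"surface {comp.name!r} borders unknown or "
                            f"non-volume compartment {bname!r}")
                    declared_tags.append(b.tag)
                if sorted(set(declared_tags)) != sorted(set(adj.volume_tags)):
                    raise ModelError(
                        f"surface {comp.name!r}: declared bordering volumes "
                        f"(tags {declared_tags}) do not match the mesh "
                        f"adjacency (tags {adj.volume_tags})")
                self.adjacency[comp.name] = adj
        # species
        for s in c.species.values():
            if s.compartment not in c.compartments:
                raise ModelError(
                    f"species {s.name!r}: unknown compartment "
                    f"{s.compartment!r}")
            if s.D < 0:
                raise ModelError(f"species {s.name!r}: negative diffusivity")
            vals = self.initial_values(s.name)
            if not np.all(np.isfinite(vals)):
                raise ModelError(
                    f"species {s.name!r}: initial condition is not finite "
                    "on its compartment")
        # parameters
        for p in c.parameters.values():
            if p.kind in ("time", "space") and not p.expression:
                raise ModelError(f"parameter {p.name!r}: kind {p.kind!r} "
                                 "requires an expression")
            if p.expression:
                expr = parse_rate(p.expression, {
                    n: self.symbols[n] for n, q in c.parameters.items()
                    if q.kind == "prestep"})
                allowed = {_T} if p.kind == "time" else set(_COORDS)
                allowed |= {self.symbols[n] for n, q in c.parameters.items()
                            if q.kind == "prestep"}
                extra = expr.free_symbols - allowed
                if extra:
                    raise ModelError(
                        f"parameter {p.name!r}: expression may only use "
                        f"{'t' if p.kind == 'time' else 'coordinates'} and "
                        f"prestep scalars, found {sorted(map(str, extra))}")
        # reactions
        self.compiled: dict[str, CompiledReaction] = {}
        for r in c.reactions.values():
            self.compiled[r.name] = self._compile_reaction(r)
        # Jacobian entries are run-constant when no derivative involves the
        # state, time, space, or a parameter that varies during a run
        # (time/space expressions, prestep scalars).  Events may still mutate
        # constants mid-run; the stepper invalidates its caches then.
        varying = {self.symbols[n] for n, p in c.parameters.items()
                   if p.kind != "constant"}
        varying |= {self.symbols[n] for n in c.species}
        varying |= {_T, *_COORDS}
        self.jacobian_constant = all(
            not (d.free_symbols & varying)
            for cr in self.compiled.values() for d in cr.derivs.values())
        self._check_unique_dof_layout()

    def _check_unique_dof_layout(self):
        # determinism contract: symbol table and orderings derive only from
        # insertion order, which dict preserves; nothing to randomize.
        self.block_order = [(comp.name, sname)
                            for comp in self.compartments.values()
                            for sname in self.species_of(comp.name)]

    def _compile_reaction(self, r: ReactionSpec) -> CompiledReaction:
        c = self.containers
        comp = c.compartments.get(r.compartment)
        if comp is None:
            raise ModelError(f"reaction {r.name!r}: unknown compartment "
                             f"{r.compartment!r}")
        if r.type == "volume" and comp.kind != "volume":
            raise ModelError(f"reaction {r.name!r}: volume reactions bind to "
                             "a volume compartment")
        if r.type != "volume" and comp.kind != "surface":
            raise ModelError(f"reaction {r.name!r}: {r.type} reactions bind "
                             "to a surface compartment")
        expr = parse_rate(r.rate, self.symbols, set(c.species))
        rate_species = [n for n in c.species
                        if self.symbols[n] in expr.free_symbols]
        involved = sorted(set(rate_species) | set(r.stoichiometry),
                          key=list(c.species).index)
        # locality rules per reaction type
        if r.type == "volume":
            for n in involved:
                if c.species[n].compartment != comp.name:
                    raise ModelError(
                        f"reaction {r.name!r}: volume reaction references "
                        f"species {n!r} outside {comp.name!r}")
        elif r.type == "surface":
            for n in involved:
                if c.species[n].compartment != comp.name:
                    raise ModelError(
                        f"reaction {r.name!r}: surface reaction references "
                        f"non-surface species {n!r}")
        else:
            borders = comp.borders
            vol_comps = {c.species[n].compartment for n in involved
                         if c.compartments[c.species[n].compartment].kind
                         == "volume"}
            for n in involved:
                sc = c.species[n].compartment
                if sc != comp.name and sc not in borders:
                    raise ModelError(
                        f"reaction {r.name!r}: species {n!r} lives in "
                        f"{sc!r}, which does not border surface "
                        f"{comp.name!r}")
            if r.type == "volume-surface" and len(vol_comps) > 1:
                raise ModelError(
                    f"reaction {r.name!r}: volume-surface reactions may "
                    "reference species from one bordering volume only")
            if r.type == "volume-surface-volume":
                if len(borders) < 2 or len(set(borders)) < 2:
                    raise ModelError(
                        f"reaction {r.name!r}: volume-surface-volume "
                        f"requires an interior surface with two bordering "
                        f"volumes; {comp.name!r} has {len(set(borders))}")
        # units
        if r.type == "volume":
            required = "uM/s"
            vol_factor = units.require_dimension(
                r.rate_unit or required, required,
                context=f"reaction {r.name!r}")
            surf_factor = 0.0
        else:
            # pure surface reactions default to surface units; membrane-flux
            # reactions to volume-side flux units (same dimension)
            default = ("molecule/(um**2*s)" if r.type == "surface"
                       else "uM*um/s")
            vol_factor = units.require_dimension(
                r.rate_unit or default, "uM*um/s",
                context=f"reaction {r.name!r}")
            surf_factor = units.require_dimension(
                r.rate_unit or default, "molecule/(um**2*s)",
                context=f"reaction {r.name!r}")
        derivs = {n: sp.diff(expr, self.symbols[n]) for n in rate_species}
        return CompiledReaction(r, expr, derivs, involved, rate_species,
                                vol_factor, surf_factor,
                                comp.name if comp.kind == "surface" else None)

    # evaluation helpers ----------------------------------------------------

    def side_of(self, surface_name: str, volume_name: str) -> int:
        """Which adjacency side (0 or 1) of a surface a volume occupies."""
        adj = self.adjacency[surface_name]
        tag = self.compartments[volume_name].tag
        if tag not in adj.volume_tags:
            raise ModelError(
                f"{volume_name!r} does not border surface {surface_name!r}")
        return adj.volume_tags.index(tag)

    def initial_values(self, species_name: str) -> np.ndarray:
        """Initial nodal values of a species on its compartment vertices."""
        s = self.species[species_name]
        sub = self.submeshes[s.compartment]
        coords = sub.coordinates
        if isinstance(s.initial, str):
            expr = parse_rate(s.initial, {})
            fn = sp.lambdify(_COORDS[:self.mesh.dim], expr, "numpy")
            vals = np.broadcast_to(
                np.asarray(fn(*coords.T), dtype=float),
                (sub.num_vertices,)).copy()
        else:
            vals = np.full(sub.num_vertices, float(s.initial))
        return vals

    def uniform_initial(self, species_name: str) -> float | None:
        """The constant initial value, or None if spatially varying."""
        s = self.species[species_name]
        if not isinstance(s.initial, str):
            return float(s.initial)
        vals = self.initial_values(species_name)
        return float(vals[0]) if np.ptp(vals) == 0 else None


def validate_model(containers: Containers, mesh: ParentMesh,
                   axisymmetric: bool = False,
                   config_extras: dict | None = None) -> Model:
    """Check all invariants and return the bound :class:`Model`."""
    return Model(containers, mesh, axisymmetric, config_extras)


def model_from_config(config, mesh: ParentMesh) -> Model:
    """One-call path from a configuration document to a validated model."""
    doc = load_config(config)
    containers = build_containers(doc)
    extras = {k: v for k, v in doc.items()
              if k not in ("compartments", "species", "parameters",
                           "reactions")}
    return validate_model(containers, mesh,
                          axisymmetric=bool(doc.get("axisymmetric", False)),
                          config_extras=extras)


# ---------------------------------------------------------------------------
# conservation-law reduction


def reduce_by_conservation(model: Model) -> tuple[Model, list[dict]]:
    """Eliminate species determined by conserved linear combinations.

    A combination of species is eligible when all members live in the same
    compartment, share one diffusion coefficient, have spatially uniform
    initial conditions, are untouched by boundary (surface-coupled) fluxes,
    and the combination is annihilated by every reaction's stoichiometry.
    For each such combination one species is eliminated and replaced in all
    rate laws by (total - sum of the others); the returned reconstruction
    map recovers the eliminated fields.  Returns the reduced model (the
    original if nothing is conserved) and the reconstruction records.
    """
    c = model.containers
    # species reached by any surface-coupled reaction are ineligible
    boundary_touched = {n for r in c.reactions.values()
                        if r.type != "volume" and
                        c.compartments[r.compartment].kind == "surface"
                        for n in set(r.stoichiometry) |
                        set(model.compiled[r.name].rate_species)}
    surface_touched = {n for r in c.reactions.values() if r.type != "volume"
                       for n in r.stoichiometry}
    records: list[dict] = []
    eliminated: dict[str, sp.Expr] = {}
    rxn_names = list(c.reactions)
    for comp in c.compartments.values():
        groups: dict[float, list[str]] = {}
        for n in model.species_of(comp.name):
            if n in boundary_touched or n in surface_touched:
                continue
            if model.uniform_initial(n) is None:
                continue
            groups.setdefault(c.species[n].D, []).append(n)
        for D, names in groups.items():
            if len(names) < 2:
                continue
            S = sp.zeros(len(names), len(rxn_names))
            for j, rn in enumerate(rxn_names):
                for i, n in enumerate(names):
                    S[i, j] = sp.nsimplify(
                        c.reactions[rn].stoichiometry.get(n, 0.0),
                        rational=True)
            for vec in S.T.nullspace():
                # eliminate the latest-declared member not yet eliminated;
                # sympy's echelon null basis guarantees distinct choices
                cand = [i for i in range(len(names))
                        if vec[i] != 0 and names[i] not in eliminated]
                if not cand:
                    continue
                idx = cand[-1]
                total = sum(float(vec[i]) * model.uniform_initial(names[i])
                            for i in range(len(names)))
                expr = (sp.Float(total) - sum(
                    vec[i] * model.symbols[names[i]]
                    for i in range(len(names))
                    if i != idx)) / vec[idx]
                eliminated[names[idx]] = sp.simplify(expr)
                records.append({
                    "species": names[idx], "compartment": comp.name,
                    "members": list(names), "coefficients":
                        [float(vec[i]) for i in range(len(names))],
                    "total": total,
                    "expression": str(eliminated[names[idx]])})
    if not eliminated:
        return model, []
    # rebuild containers with eliminated species substituted out
    new_species = {n: s for n, s in c.species.items() if n not in eliminated}
    subs = {model.symbols[n]: e for n, e in eliminated.items()}
    new_rxns: dict[str, ReactionSpec] = {}
    for rn, r in c.reactions.items():
        expr = model.compiled[rn].expr.xreplace(subs)
        stoich = {n: v for n, v in r.stoichiometry.items()
                  if n not in eliminated}
        if not stoich:
            continue   # reaction acted only on eliminated species' images
        new_rxns[rn] = ReactionSpec(r.name, r.type, r.compartment,
                                    sp.sstr(expr), stoich, r.rate_unit)
    reduced_containers = Containers(dict(c.compartments), new_species,
                                    dict(c.parameters), new_rxns)
    reduced = Model(reduced_containers, model.mesh, model.axisymmetric,
                    model.config_extras)
    reduced.reduction = [(rec["species"],
                          sp.sympify(rec["expression"]), rec)
                         for rec in records]
    return reduced, records


# ---------------------------------------------------------------------------
# well-mixed (0D) reduction


@dataclass
class ODESystem:
    """Well-mixed reduction: one state per species, area/volume-scaled fluxes."""

    species: list[str]
    y0: np.ndarray
    rhs: callable
    measures: dict[str, float]

    def __call__(self, t, y):
        return self.rhs(t, y)


def reduce_to_ode(model: Model, measures: dict[str, float] | None = None
                  ) -> ODESystem:
    """Build the well-mixed ODE right-hand side of the model.

    Boundary fluxes are scaled by (surface measure)/(volume measure) with
    the same unit conversions as the PDE assembly.  Space-expression
    parameters have no well-mixed meaning and raise a model error; prestep
    scalars are held at their initial values.
    """
    for p in model.parameters.values():
        if p.kind == "space":
            raise ModelError(
                f"parameter {p.name!r} is a space-expression; the model has "
                "no well-mixed reduction")
    if measures is None:
        measures = {name: sub.measure()
                    for name, sub in model.submeshes.items()}
    names = list(model.species)
    index = {n: i for i, n in enumerate(names)}
    y0 = np.array([np.mean(model.initial_values(n)) for n in names])
    # resolve parameters: constants/prestep now; time-expressions per call
    const_vals: dict[sp.Symbol, float] = {}
    time_exprs: dict[sp.Symbol, sp.Expr] = {}
    prestep_syms = {model.symbols[n] for n, p in model.parameters.items()
                    if p.kind == "prestep"}
    for n, p in model.parameters.items():
        s = model.symbols[n]
        if p.kind == "time":
            time_exprs[s] = parse_rate(p.expression, {
                q: model.symbols[q] for q in model.parameters
                if model.parameters[q].kind == "prestep"})
        else:
            const_vals[s] = p.value
    terms = []
    for cr in model.compiled.values():
        expr = cr.expr.xreplace(const_vals)
        args = [model.symbols[n] for n in names] + [_T]
        tsubs = {s: e.xreplace(const_vals) for s, e in time_exprs.items()}
        expr = expr.xreplace(tsubs).xreplace(
            {s: const_vals.get(s, 0.0) for s in prestep_syms
             if s in expr.free_symbols})
        fn = sp.lambdify(args, expr, "numpy")
        coeffs = np.zeros(len(names))
        r = cr.spec
        if r.type == "volume":
            for n, st in r.stoichiometry.items():
                coeffs[index[n]] = st * cr.volume_factor   # uM/s
        else:
            area = measures[r.compartment]
            for n, st in r.stoichiometry.items():
                comp = model.compartments[model.species[n].compartment]
                if comp.kind == "volume":
                    vol = measures[comp.name]
                    coeffs[index[n]] = st * cr.volume_factor * area / vol
                else:
                    coeffs[index[n]] = st * cr.surface_factor
        terms.append((fn, coeffs))

    def rhs(t, y):
        dy = np.zeros_like(y)
        for fn, coeffs in terms:
            dy += coeffs * float(fn(*y, t))
        return dy

    return ODESystem(names, y0, rhs, dict(measures))
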