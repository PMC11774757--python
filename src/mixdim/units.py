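"""Minimal unit algebra for model validation.

The package works in a fixed base system: micrometre (``um``) for length,
second (``s``) for time and ``molecule`` for amount.  Volume concentrations
are expressed in micromolar with the fixed conversion

    1 uM = 602.214076 molecule / um**3

(the Avogadro constant scaled to these units), surface concentrations in
``molecule/um**2``.  A :class:`Unit` is a scale factor times a monomial in
the three base units; that is all the dimensional bookkeeping the model
layer needs -- rates are *checked* against the unit the binding compartment
requires, not inferred term by term.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import sympy as sp

from .errors import UnitError

#: molecules per um^3 in a 1 uM solution (Avogadro's number x 1e-21).
MOLECULES_PER_UM3: float = 602.214076

_BASE = ("um", "s", "molecule")
_base_syms = sp.symbols(_BASE, positive=True)


@dataclass(frozen=True)
class Unit:
    """A physical unit: ``factor`` x um^a s^b molecule^c in the base system."""

    factor: float
    dims: tuple[Fraction, Fraction, Fraction]

    def __mul__(self, other: "Unit") -> "Unit":
        return Unit(self.factor * other.factor,
                    tuple(a + b for a, b in zip(self.dims, other.dims)))

    def __truediv__(self, other: "Unit") -> "Unit":
        return Unit(self.factor / other.factor,
                    tuple(a - b for a, b in zip(self.dims, other.dims)))

    def __pow__(self, n: int) -> "Unit":
        return Unit(self.factor ** n, tuple(a * n for a in self.dims))

    def same_dimension(self, other: "Unit") -> bool:
        return self.dims == other.dims

    def conversion_factor(self, other: "Unit") -> float:
        """Multiplier turning a value in ``self`` into a value in ``other``."""
        if not self.same_dimension(other):
            raise UnitError(f"incompatible dimensions: {self} vs {other}")
        return self.factor / other.factor

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        mono = " ".join(f"{n}^{d}" for n, d in zip(_BASE, self.dims) if d != 0)
        return f"{self.factor:g} {mono or '1'}"


DIMENSIONLESS = Unit(1.0, (Fraction(0), Fraction(0), Fraction(0)))

_NAMED: dict[str, Unit] = {
    "um": Unit(1.0, (Fraction(1), Fraction(0), Fraction(0))),
    "s": Unit(1.0, (Fraction(0), Fraction(1), Fraction(0))),
    "molecule": Unit(1.0, (Fraction(0), Fraction(0), Fraction(1))),
    "molecules": Unit(1.0, (Fraction(0), Fraction(0), Fraction(1))),
    # 1 uM = 602.214076 molecule/um^3
    "uM": Unit(MOLECULES_PER_UM3, (Fraction(-3), Fraction(0), Fraction(1))),
    "dimensionless": DIMENSIONLESS,
    "1": DIMENSIONLESS,
}


def parse_unit(text: str | Unit | None) -> Unit:
    """Parse a unit string such as ``"uM*um/s"`` or ``"molecule/(um**2*s)"``.

    The grammar is any sympy-parsable product/quotient/power of the named
    units (um, s, molecule, uM) and numeric literals.
    """
    if text is None:
        return DIMENSIONLESS
    if isinstance(text, Unit):
        return text
    try:
        expr = sp.sympify(text, locals={n: s for n, s in
                                        zip(_BASE, _base_syms)} | {
                                            "uM": sp.Symbol("uM", positive=True),
                                            "molecules": _base_syms[2],
                                            "dimensionless": sp.Integer(1)})
    except (sp.SympifyError, SyntaxError, TypeError) as exc:
        raise UnitError(f"cannot parse unit {text!r}: {exc}") from None
    unit = Unit(1.0, (Fraction(0),) * 3)
    expr = sp.nsimplify(expr, rational=True) if expr.is_number else expr
    for factor, exponent in expr.as_powers_dict().items():
        if factor.is_number:
            unit = unit * Unit(float(factor) ** float(exponent), (Fraction(0),) * 3)
            continue
        name = str(factor)
        if name not in _NAMED:
            raise UnitError(f"unknown unit symbol {name!r} in {text!r}")
        try:
            n = Fraction(str(exponent))
        except ValueError:
            raise UnitError(f"non-rational exponent in unit {text!r}") from None
        if n.denominator == 1:
            unit = unit * (_NAMED[name] ** int(n))
        else:  # fractional powers never appear in practice but keep it exact
            base = _NAMED[name]
            unit = unit * Unit(base.factor ** float(n),
                               tuple(d * n for d in base.dims))
    return unit


def require_dimension(declared: str | Unit, required: str | Unit, *,
                      context: str = "") -> float:
    """Check that ``declared`` has the dimension of ``required``.

    Returns the factor converting declared-unit values to required-unit
    values; raises :class:`UnitError` naming the context otherwise.
    """
    du, ru = parse_unit(declared), parse_unit(required)
    if not du.same_dimension(ru):
        where = f" in {context}" if context else ""
        raise UnitError(
            f"unit mismatch{where}: declared {declared!r}, required "
            f"dimension of {required!r}")
    return du.conversion_factor(ru)
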