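"""Exception hierarchy.

Every failure mode surfaced by the library derives from :class:`MixdimError`
so callers can catch one base class; subclasses distinguish file-format
problems, geometry defects, model/validation errors and solver failures.
"""


class MixdimError(Exception):
    """Base class for all mixdim errors."""


class FormatError(MixdimError):
    """Unreadable or wrong-dialect input file."""


class GeometryError(MixdimError):
    """Degenerate or inconsistent geometry (zero-measure simplex, bad radii...)."""


class MeshConsistencyError(MixdimError):
    """Tagged entities violate mesh topology contracts."""


class ModelError(MixdimError):
    """Invalid model construct (unknown tag, bad adjacency, banned expression...)."""


class SchemaError(ModelError):
    """Configuration document does not conform to the model schema."""


class UnitError(ModelError):
    """Dimensional inconsistency in a declared unit."""


class EvaluationError(MixdimError):
    """A rate or parameter expression evaluated to a non-finite value."""


class NonlinearDivergenceError(MixdimError):
    """Newton iteration failed to converge (caught by step control)."""


class StepFailureError(MixdimError):
    """A time step could not be completed within the restart budget."""
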