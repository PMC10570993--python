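"""Exception hierarchy shared across npcsim modules."""


class NpcsimError(Exception):
    """Base class for all npcsim errors."""


class FormatError(NpcsimError):
    """A file or table does not conform to the documented schema."""


class ValidationError(NpcsimError, ValueError):
    """An input value violates a documented precondition or invariant."""


class LookupError_(NpcsimError, KeyError):
    """A requested (nucleoporin, terminus) label is absent from the reference unit."""


class FitError(NpcsimError):
    """Geometric fitting failed (too few points or degenerate configuration)."""


class InapplicableError(NpcsimError):
    """The operation needs at least two axial sides (subcomplexes) and the model has one."""


class ConvergenceError(NpcsimError):
    """The spring relaxation did not reach the equilibrium residual tolerance."""


class DegenerateGeometryError(NpcsimError):
    """A node sits (numerically) on the central axis, so no radial direction exists."""
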