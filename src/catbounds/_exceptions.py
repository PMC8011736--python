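"""Exception hierarchy for catbounds."""


class CatboundsError(Exception):
    """Base class for all catbounds errors."""


class ParameterError(CatboundsError, ValueError):
    """Invalid shape parameters (e.g. non-positive Beta alpha/beta)."""


class DomainError(CatboundsError, ValueError):
    """Positions or intervals outside the attribute space, or a >= b."""


class DataError(CatboundsError, ValueError):
    """Empirical samples unusable (out of range, too few)."""


class DegenerateGroupError(CatboundsError, ValueError):
    """A group interval carries (numerically) zero population mass."""


class SolverError(CatboundsError, RuntimeError):
    """Boundary dynamics or fixed-point search failed to converge."""
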