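"""Exception types shared across the package."""


class RPFluxError(Exception):
    """Base class for all package-specific errors."""


class MapValidationError(RPFluxError, ValueError):
    """A signaling map violates its schema or an internal invariant."""


class UnknownPathwayError(RPFluxError, KeyError):
    """A pathway id was requested that does not exist in the map."""


class ContractError(RPFluxError, ValueError):
    """Caller-supplied inputs are mutually inconsistent (e.g. mismatched ids)."""


class DegenerateInputError(RPFluxError, ValueError):
    """Input is formally valid but degenerate for the requested computation."""


class DomainError(RPFluxError, ValueError):
    """A numeric argument lies outside its documented domain."""
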