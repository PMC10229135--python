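"""Exception hierarchy shared across the package."""


class AllopharmError(Exception):
    """Base class for package errors."""


class DomainError(AllopharmError, ValueError):
    """An input value lies outside the physically meaningful domain."""


class ParameterError(AllopharmError, ValueError):
    """A model parameter is invalid (non-finite, wrong sign, out of bounds)."""


class ShapeError(AllopharmError, ValueError):
    """Array inputs have mismatched shapes or grids."""


class DegenerateGeometryError(AllopharmError, ValueError):
    """A geometric operation is undefined (collinear atoms, single frame...)."""


class ConfigurationError(AllopharmError, ValueError):
    """An invalid configuration was supplied (unknown key, bad combination)."""


class EmptyResultError(AllopharmError, RuntimeError):
    """A computation produced no usable output (e.g. no bin passed a cutoff)."""
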