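"""Exception hierarchy.

All package errors derive from :class:`RingflowError` so callers (and the
CLI) can distinguish configuration, input-validation and geometry failures
from unexpected bugs.
"""


class RingflowError(Exception):
    """Base class for all errors raised by ringflow."""


class ConfigError(RingflowError):
    """Invalid model parameters or run configuration."""


class InputDomainError(RingflowError):
    """A measured input violates the model's physical domain.

    Carries enough context (field name, tracheid position, source line)
    to point at the offending measurement.
    """

    def __init__(self, message: str, *, field: str | None = None,
                 position: int | None = None, source: str | None = None):
        parts = [message]
        if field is not None:
            parts.append(f"field={field!r}")
        if position is not None:
            parts.append(f"position={position}")
        if source is not None:
            parts.append(f"source={source}")
        super().__init__("; ".join(parts))
        self.field = field
        self.position = position
        self.source = source


class DegenerateGeometryError(RingflowError):
    """Derived pit geometry cannot support a resistance computation."""
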