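"""Exception types shared across driftscan modules."""


class DriftscanError(Exception):
    """Base class for package errors."""


class ArgumentError(DriftscanError, ValueError):
    """Invalid argument to an operation."""


class EmptyPanelError(DriftscanError):
    """A founder panel ended up with zero segregating sites."""


class PedigreeError(DriftscanError):
    """A pedigree could not be generated or is inconsistent."""


class ConsistencyError(DriftscanError):
    """Inputs that must agree (labels, site sets, sizes) do not."""
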