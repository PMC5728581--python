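"""Exception types shared across the package."""


class NucleoslideError(Exception):
    """Base class for all package-specific errors."""


class ParseError(NucleoslideError):
    """A structure or table file could not be parsed."""


class TopologyError(NucleoslideError):
    """Bead/chain layout violates the coarse-grained topology rules."""


class GeometryError(NucleoslideError):
    """A geometric quantity cannot be evaluated (degenerate input)."""


class WindowError(NucleoslideError):
    """A requested base pair lies outside the valid analysis window."""
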