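"""Exception hierarchy."""


class HedError(Exception):
    """Base class for all package errors."""


class FormatError(HedError):
    """A file could not be parsed in the requested format."""


class ValidationError(HedError):
    """Parsed data violate a structural invariant."""


class SelectionError(HedError):
    """An atom/residue selection is empty, too small or degenerate."""


class FitError(HedError):
    """A fit cannot be attempted (e.g. too few observations)."""
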