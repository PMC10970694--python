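"""Exception hierarchy and warnings.

All package-specific failures derive from :class:`ParaporeError` so callers
(and the CLI) can distinguish data/usage problems from genuine bugs.
"""


class ParaporeError(Exception):
    """Base class for all parapore errors."""


class FormatError(ParaporeError):
    """A file could not be parsed (message names the offending line)."""


class ShapeError(ParaporeError):
    """Frame/topology atom-count mismatch or otherwise inconsistent shapes."""


class SelectionError(ParaporeError):
    """A selection or residue/atom lookup failed."""


class GeometryError(ParaporeError):
    """Invalid or degenerate geometry parameters."""


class ConfigError(ParaporeError):
    """Invalid analysis configuration (wrong atom counts, bad bounds...)."""


class ParameterError(ParaporeError):
    """A numeric parameter is out of its valid range."""


class EmptySelectionWarning(UserWarning):
    """A selection matched zero atoms (warning, not an error)."""
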