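"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`CaifpError`
so callers (and the CLI) can distinguish data problems from bugs.
"""


class CaifpError(Exception):
    """Base class for all caifp errors."""


class ParseError(CaifpError):
    """A structure file could not be parsed; message names the offending record."""


class FormatError(CaifpError):
    """Unsupported or malformed file format."""


class AmbiguityError(CaifpError):
    """A selector matched zero or more than one candidate."""


class InconsistencyError(CaifpError):
    """Two objects that must share a binding-site axis (or length) do not."""


class MissingResidueError(CaifpError):
    """A binding-site residue is absent from the receptor."""


class AlignmentError(CaifpError):
    """Too few paired atoms for a rigid superposition."""


class UsageError(CaifpError):
    """Empty or otherwise unusable input to an operation."""


class InputError(CaifpError):
    """Structures with incompatible atom composition."""


class GenerationError(CaifpError):
    """A synthetic fixture request is geometrically infeasible."""
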