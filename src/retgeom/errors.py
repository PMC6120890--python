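"""Exception hierarchy for retgeom.

All analysis-level failures derive from :class:`RetgeomError` so callers
(and the CLI) can distinguish bad input from programming errors.
"""


class RetgeomError(Exception):
    """Base class for all retgeom errors."""


class ParseError(RetgeomError):
    """A coordinate file could not be parsed under the requested dialect."""


class UnsupportedFormatError(RetgeomError):
    """An unknown file-format tag was requested."""


class FormattingError(RetgeomError):
    """A field does not fit the fixed columns of the output format."""


class UndefinedGeometryError(RetgeomError):
    """Degenerate geometry (e.g. collinear points in a dihedral)."""


class UnsupportedHybridizationError(RetgeomError):
    """Hydrogen placement requested for a carbon that is not sp2 with two heavy neighbors."""


class InsufficientAtomsError(RetgeomError):
    """Too few atoms (or common atom pairs) for a superposition."""


class IncompleteChromophoreError(RetgeomError):
    """A polyene path atom is missing from the model."""


class IncompatibleProfilesError(RetgeomError):
    """Two helicity profiles do not share the same bond labels."""


class AtomNotFoundError(RetgeomError):
    """A requested atom or water could not be resolved in the model."""


class InsufficientReplicatesError(RetgeomError):
    """A significance test needs at least two replicate structures."""


class NoCalibrationError(RetgeomError):
    """Damage calibration is degenerate (all sentinel B shifts zero)."""


class FitFailureError(RetgeomError):
    """Nonlinear fit failed to converge from every start."""


class UnreachableFractionError(RetgeomError):
    """Requested damage fraction exceeds the fitted plateau."""


class ConstructionError(RetgeomError):
    """A synthetic-structure specification cannot be realized."""
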