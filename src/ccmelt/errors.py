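"""Exception hierarchy for ccmelt.

Every error raised by the package derives from :class:`CcmeltError`, so
callers (and the CLI) can catch one base class. The subclasses mirror the
distinct failure modes of each analysis stage.
"""


class CcmeltError(Exception):
    """Base class for all ccmelt errors."""


class PositionError(CcmeltError):
    """A native residue position is absent from a sequence or fragment."""


class ValidationError(CcmeltError):
    """Input contradicts its own declared content (e.g. wild-type mismatch)."""


class CoverageError(CcmeltError):
    """A heptad annotation does not cover the requested residue range."""


class AlignmentError(CcmeltError):
    """Two sequences or series cannot be aligned (length mismatch)."""


class AlphabetError(CcmeltError):
    """A residue code outside the 20-letter amino-acid alphabet."""


class DomainError(CcmeltError):
    """A numeric argument outside its physical domain (e.g. conc <= 0)."""


class DegenerateCurveError(CcmeltError):
    """A melting curve with no signal range (max == min) cannot be normalized."""


class ParameterError(CcmeltError):
    """An algorithm parameter is invalid (e.g. even smoothing window)."""


class GridError(CcmeltError):
    """A temperature or wavelength grid is too short or not increasing."""


class FitError(CcmeltError):
    """Nonlinear fitting failed to converge; message carries diagnostics."""


class SampleSizeError(CcmeltError):
    """Too few observations for the requested statistical test."""


class ReportError(CcmeltError):
    """A report cannot be assembled (e.g. missing reference condition)."""


class FormatError(CcmeltError):
    """A file does not conform to its expected dialect."""


class AtomError(CcmeltError):
    """A required atom is missing from a structure or trajectory frame."""
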