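"""Exception hierarchy shared across the package."""


class LFRamanError(Exception):
    """Base class for all package errors."""


class ParseError(LFRamanError):
    """A spectrum or manifest file could not be parsed."""


class DegenerateDataError(LFRamanError):
    """Input data too small or too trivial to be processed (e.g. < 8 points)."""


class GridError(LFRamanError):
    """Wavenumber grids of spectra do not match where they must."""


class ExtrapolationError(GridError):
    """A requested grid extends beyond the measured wavenumber range."""


class OrderingError(LFRamanError):
    """A series axis (time or temperature) is not strictly increasing."""


class MetadataError(LFRamanError):
    """Required metadata (typically temperature) is missing."""


class RepresentationError(LFRamanError):
    """Operation applied to a spectrum in the wrong representation."""


class DomainError(LFRamanError):
    """Numeric argument outside the physically meaningful domain."""


class FitError(LFRamanError):
    """A model fit could not be set up or evaluated."""


class NoContrastError(LFRamanError):
    """Band-area anchors coincide; transformation rate is undefined."""


class IncompleteTransformationError(LFRamanError):
    """The transformation never reaches half-conversion."""
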