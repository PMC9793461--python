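"""Exception hierarchy for the IVR processing pipeline.

All pipeline errors derive from :class:`IVRError` so callers can catch
one base class at the CLI boundary while tests assert the specific type.
"""


class IVRError(Exception):
    """Base class for all ivrtools errors."""


class SpectraFormatError(IVRError):
    """A spectral file does not conform to the expected CSV layout."""


class SpectraDataError(IVRError):
    """A spectral file parsed but violates a data invariant (e.g. a
    vessel whose time points do not share one wavelength grid)."""


class GridRangeError(IVRError):
    """A wavelength was requested outside the span of the available grid
    (resampling would require extrapolation)."""


class CalibrationError(IVRError):
    """A probe standard cannot support quantification (e.g. zero
    absorbance at the analysis wavelength)."""


class WavelengthSelectionError(IVRError):
    """No usable derivative extreme exists in the requested search
    window (the standard derivative is flat throughout)."""


class KineticsFitError(IVRError):
    """A release-kinetics fit failed or the data are degenerate.

    Carries the initializer state so the failure is reproducible.
    """

    def __init__(self, message: str, initializer: dict | None = None):
        super().__init__(message)
        self.initializer = dict(initializer) if initializer else {}


class ProfileMismatchError(IVRError):
    """Two release profiles cannot be combined or compared (different
    time grids or method tags)."""


class ScenarioError(IVRError):
    """An unknown simulation scenario name was requested."""
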