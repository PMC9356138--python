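"""Exception types shared across the pipeline stages."""


class CalibrationError(ValueError):
    """Wavenumber calibration missing or inconsistent with the image data."""


class PackingError(RuntimeError):
    """Phantom geometry could not be placed within the bounded retry budget."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested model (e.g. k > valid pixels)."""


class ConditioningError(ValueError):
    """Reference spectra are collinear (or nearly so) on the stack's axis."""


class IncompatibilityError(ValueError):
    """Arrays that must share a grid or axis do not."""
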