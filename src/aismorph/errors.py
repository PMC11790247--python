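"""Exception types shared across the package."""


class AismorphError(Exception):
    """Base class for all package-specific errors."""


class NoSignalError(AismorphError):
    """A channel has no usable contrast (flat or all-zero profile)."""


class NoObjectError(AismorphError):
    """No suprathreshold pixel on the normalized profile."""


class ZeroVarianceError(AismorphError):
    """Autocorrelation of a constant profile is undefined."""


class AperiodicError(AismorphError):
    """No post-minimum local maximum in the autocorrelation curve."""


class PathOutsideCanvasError(AismorphError):
    """A rendering path (plus transverse band) exits the image canvas."""


class UndersampledError(AismorphError):
    """Sample spacing too coarse for the requested periodic structure."""


class FeatureFailure(AismorphError):
    """An AP waveform feature could not be computed on this sweep."""
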