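"""Named exceptions raised by the analysis stages.

Each failure mode a caller may want to handle gets its own class so that
pipeline logs and tests can distinguish them.
"""


class GliavascError(Exception):
    """Base class for all package errors."""


class ConstantImageError(GliavascError):
    """Image has no intensity variation; thresholding is undefined."""


class RegistrationError(GliavascError):
    """Frame sequence cannot be registered (e.g. a degenerate constant frame)."""


class DepthWindowError(GliavascError):
    """Stack does not contain the requested cortical depth window."""


class NoParenchymaError(GliavascError):
    """Vessel mask covers the whole field; no extravascular pixels remain."""


class NormalizationError(GliavascError):
    """Reference group is empty or has non-positive mean intensity."""


class IndeterminateContactError(GliavascError):
    """Line profile supports neither a gap measurement nor an overlap call."""


class ZeroVarianceError(GliavascError):
    """A channel is constant inside the ROI; correlation is undefined."""


class EmptyMaskError(GliavascError):
    """A required binary mask is empty."""


class SceneError(GliavascError):
    """Synthetic scene configuration is invalid or unrenderable."""


class MissingChannelError(GliavascError):
    """A stack lacks a channel role required by the analysis."""


class CalibrationError(GliavascError):
    """A stack lacks valid physical calibration."""


class EmptyManifestError(GliavascError):
    """The input manifest lists no images."""
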