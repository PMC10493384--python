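"""Exception hierarchy shared across the toolkit."""


class PhantomForgeError(Exception):
    """Base class for all toolkit errors."""


class FormatError(PhantomForgeError):
    """A file or on-disk structure does not conform to the expected format."""


class GeometryError(PhantomForgeError):
    """Two objects that must share voxel geometry do not, or an ROI leaves the volume."""


class ConfigError(PhantomForgeError):
    """Invalid or inconsistent configuration (schemes, plans, registration settings)."""


class SegmentationError(PhantomForgeError):
    """A compartment could not be segmented (e.g. no usable region-growing seed)."""


class FitError(PhantomForgeError):
    """Calibration fitting is impossible (too few levels, degenerate data)."""


class RegistrationError(PhantomForgeError):
    """Registration failed: no overlap between fields of view or diverged metric."""


class SpecError(PhantomForgeError):
    """A synthetic-phantom specification is geometrically impossible."""
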