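"""Exception hierarchy for the woifc pipeline."""


class WoifcError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(WoifcError):
    """Invalid or inconsistent run configuration."""


class LayoutError(WoifcError):
    """Raw stack layout inconsistent with the declared channel interleave,
    or a synthetic region layout that does not fit the requested shape."""


class MaskError(WoifcError):
    """Mask violates its invariants (overlapping hemispheres, shape mismatch)."""


class SpectroscopyError(WoifcError):
    """Rank-deficient or otherwise unusable extinction/pathlength system."""


class PreprocessError(WoifcError):
    """A preprocessing step received input violating its preconditions."""


class ParcellationError(WoifcError):
    """Degenerate data or invalid parameters for parcellation/clustering."""


class StatsError(WoifcError):
    """Invalid input to a statistical test."""
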