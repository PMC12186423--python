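"""Exception hierarchy.

Everything raised on purpose derives from :class:`SeedScreenError` so callers
(and the batch runner) can separate expected analysis failures from bugs.
"""


class SeedScreenError(Exception):
    """Base class for all errors raised by seedscreen."""


class ParameterError(SeedScreenError, ValueError):
    """A user-supplied parameter is out of range or inconsistent."""


class ConstantImageError(SeedScreenError):
    """Automatic thresholding was asked for on an image with a single value."""


class NoRegionsError(SeedScreenError):
    """No foreground regions were found where at least one is required."""


class NoMarkersError(SeedScreenError):
    """The radial threshold left no watershed marker cores."""


class ChannelMismatchError(SeedScreenError):
    """Marker-channel count exceeds the total count from the brightfield channel."""


class BimodalityError(SeedScreenError):
    """Automatic b* thresholding refused to split a unimodal colour population."""


class SceneError(SeedScreenError):
    """Synthetic scene generation could not satisfy the layout constraints."""


class BatchError(SeedScreenError):
    """Batch input discovery failed (empty manifest, unreadable directory...)."""
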