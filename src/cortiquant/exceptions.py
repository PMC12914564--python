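"""Exception hierarchy for cortiquant.

All pipeline-level failures derive from :class:`CortiquantError` so callers
can catch one base class; specific subclasses mark which stage rejected the
input.
"""


class CortiquantError(Exception):
    """Base class for all cortiquant errors."""


class PhantomSpecError(CortiquantError, ValueError):
    """A phantom specification is internally inconsistent (e.g. lesion
    larger than the tissue footprint, negative density)."""


class EmptyMaskError(CortiquantError):
    """DAPI masking found no foreground pixels."""


class MissingChannelError(CortiquantError, KeyError):
    """A required fluorescence channel is absent from a slice image."""


class SliceOrderError(CortiquantError, ValueError):
    """Slices cannot be ordered (duplicate ids or missing AP metadata)."""


class ProfileError(CortiquantError, ValueError):
    """An area or intensity profile violates its preconditions (too few
    samples, zero total intensity, non-monotone positions)."""


class RoiError(CortiquantError, ValueError):
    """A region of interest falls outside the image or tissue."""


class NormalizationError(CortiquantError, ValueError):
    """A normalization baseline is zero or undefined."""


class ConfigError(CortiquantError, ValueError):
    """A run configuration contains unknown or invalid keys."""
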