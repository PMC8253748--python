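"""Exception hierarchy for the vertebral-compression pipeline."""


class SpineVCError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SpineVCError):
    """A configuration value violates an invariant; the message names the
    violated constraint."""


class ValidationError(SpineVCError):
    """Runtime input failed validation (shape/range/length mismatch)."""


class CornerDetectionError(SpineVCError):
    """A vertebral body has fewer than four distinguishable corners.

    Feeds condition 2 of the accurate-segmentation filter.
    """


class PartitionError(SpineVCError):
    """Left/right vertex partition is malformed (e.g. all four vertexes on
    one side of the dividing line)."""


class ComputationError(SpineVCError):
    """A measurement could not be computed (e.g. non-positive neighbour
    heights in the compression formula)."""
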