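"""Exception hierarchy for the voxscore pipeline.

Every error raised by the library derives from :class:`VoxscoreError` so
callers (and the CLI) can catch pipeline failures without masking bugs.
"""


class VoxscoreError(Exception):
    """Base class for all voxscore errors."""


class InputFormatError(VoxscoreError):
    """An input file could not be read or has an unsupported format."""


class ParameterError(VoxscoreError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(VoxscoreError):
    """The input is formally valid but carries no usable information
    (e.g. an all-zero frame passed to an AR fit)."""


class InsufficientDataError(VoxscoreError):
    """Too few frames / samples / vectors to compute the requested quantity."""


class MissingFormantError(VoxscoreError):
    """Fewer than three qualifying resonances were found in a frame."""


class DivergenceError(VoxscoreError):
    """Training produced a non-finite loss; a smaller learning rate is advised."""


class UnfittedModelError(VoxscoreError):
    """The model is missing fitted state (e.g. normalization parameters)."""
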