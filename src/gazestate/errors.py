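"""Exception hierarchy for the gazestate pipeline.

Every error raised by the library derives from :class:`GazeStateError`;
the CLI maps subclasses onto distinct exit codes.
"""


class GazeStateError(Exception):
    """Base class for all gazestate errors."""


class InvalidSampleError(GazeStateError):
    """A gaze sample has non-finite or out-of-range coordinates."""


class EmptyTrialError(GazeStateError):
    """A trial contains no retained samples."""


class InsufficientDataError(GazeStateError):
    """Too few samples or units for the requested computation."""


class SchemaError(GazeStateError):
    """A file or table does not match the expected schema (header, AOI set,
    missing indicator columns...)."""


class DegenerateDataError(GazeStateError):
    """The data admit no meaningful fit (all columns constant, a single
    condition present, unpaired participants...)."""


class PairingError(DegenerateDataError):
    """Participants are not paired across the two conditions."""
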