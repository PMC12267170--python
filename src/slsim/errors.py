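"""Exception types raised by the simulator.

Every contract violation raises a subclass of :class:`SlsimError` so callers
can distinguish protocol failures from programming errors.
"""


class SlsimError(Exception):
    """Base class for all simulator errors."""


class UnknownLabelError(SlsimError):
    """A class label outside the declared six-class set."""


class ImageSizeError(SlsimError):
    """Requested image geometry below the supported minimum."""


class PartitionError(SlsimError):
    """Invalid split ratios, negative counts, or inconsistent partitions."""


class PreprocessError(SlsimError):
    """Invalid geometry arguments to a preprocessing operation."""


class KeyExchangeError(SlsimError):
    """Public key outside the valid range or malformed group."""


class MaskingError(SlsimError):
    """Missing pair seeds or inconsistent masked updates."""


class MissingParticipantError(SlsimError):
    """A declared participant's update is absent, so masks cannot cancel."""


class LedgerError(SlsimError):
    """Chain integrity violations and vote bookkeeping errors."""


class UncommittedPayloadError(LedgerError):
    """Attempt to append a round record that did not reach quorum."""


class ProtocolError(SlsimError):
    """Swarm round aborted: participation below minimum or commit failure."""


class TrainingError(SlsimError):
    """Empty shards, shape mismatches, or invalid training configuration."""


class MetricsError(SlsimError):
    """Degenerate inputs to an evaluation metric (e.g. single-class ROC)."""
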