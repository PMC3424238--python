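"""Exception hierarchy for the episeq pipeline."""


class EpiseqError(Exception):
    """Base class for all episeq errors."""


class FormatError(EpiseqError):
    """Malformed or inconsistent input file."""


class MissingTrackError(EpiseqError):
    """A feature encoder requires a per-residue track that is absent."""


class UndefinedFeatureError(EpiseqError):
    """A composition-type feature has an empty denominator (all-X window)."""


class NotFittedError(EpiseqError):
    """Prediction requested from an unfitted model."""
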