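"""Exception hierarchy for the nirscomp pipeline."""


class NirscompError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NirscompError, ValueError):
    """Invalid configuration value (bad rate, cutoff, label, ...)."""


class ShapeError(NirscompError, ValueError):
    """Mismatched series lengths or malformed array shapes."""


class UnpaddablePrefixError(NirscompError, ValueError):
    """A missing sample falls inside the first `lookback` positions."""


class FilterLengthError(NirscompError, ValueError):
    """Series too short for stable zero-phase filtering."""


class DegenerateChannelError(NirscompError, ValueError):
    """A channel is constant where variability is required (CBSI alpha)."""


class WindowError(NirscompError, ValueError):
    """Analysis window too small or series shorter than one window."""


class SchemaError(NirscompError, ValueError):
    """CSV/manifest does not match the documented column schema."""


class ParseError(NirscompError, ValueError):
    """Malformed cell or ragged row in a trial CSV; carries a line number."""


class TrainingError(NirscompError, ValueError):
    """Classifier cannot be trained (single class, folds > rows, ...)."""
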