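"""Exception hierarchy shared by all gaitwb modules."""


class GaitWBError(Exception):
    """Base class for all gaitwb errors."""


class FormatError(GaitWBError):
    """A file does not match the declared schema (missing columns, bad header)."""


class DataError(GaitWBError):
    """Well-formed input whose content is invalid (non-monotone time, overlap...)."""


class ParameterError(GaitWBError):
    """A parameter is outside its admissible range."""


class DegenerateSignalError(GaitWBError):
    """A signal carries no usable information (zero variance, all flat)."""


class TuningError(GaitWBError):
    """Threshold tuning failed for a subject or side."""


class ConfigError(GaitWBError):
    """A configuration file or scenario description is invalid."""


class LyingOnsetNotFound(GaitWBError):
    """No static ~1 g posture of sufficient duration was found.

    Callers may catch this and proceed from t=0 with a warning.
    """
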