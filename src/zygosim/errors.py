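"""Exception hierarchy shared across the package."""


class ZygosimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ZygosimError):
    """A configuration value is missing, inconsistent, or out of range."""


class DetectionError(ZygosimError):
    """An image-analysis step found no acceptable target."""


class CalibrationError(ZygosimError):
    """The brightness/contrast-to-height calibration cannot be applied."""


class FsmError(ZygosimError):
    """The injection sequencer was driven with an undefined transition."""
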