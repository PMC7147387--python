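"""Exception hierarchy shared by all pipeline stages."""


class SweepscanError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(SweepscanError):
    """Invalid parameter or configuration file."""


class InputError(SweepscanError):
    """Malformed or inconsistent input data."""


class DegenerateDataError(SweepscanError):
    """A statistic is undefined on the given data (e.g. zero variance)."""
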