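"""Exception hierarchy; each class maps to a CLI exit status."""


class CensusmortError(Exception):
    """Base class for package errors."""

    exit_code = 1


class ConfigurationError(CensusmortError):
    """Invalid configuration: bad probability vectors, unknown keys, missing files."""

    exit_code = 2


class DataIntegrityError(CensusmortError):
    """Inconsistent microdata: orphan deaths, malformed life-table files."""

    exit_code = 3


class NumericalError(CensusmortError):
    """Numerical failure: singular Hessian, non-finite likelihood."""

    exit_code = 4
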