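"""Exception hierarchy. CLI maps these onto exit codes (see ``dyncore.cli``)."""


class DyncoreError(Exception):
    """Base class for all dyncore errors."""


class ConfigError(DyncoreError, ValueError):
    """Invalid configuration or parameter value (CLI exit code 2)."""


class DataFormatError(DyncoreError, ValueError):
    """Malformed input file or inconsistent data structure (CLI exit code 3)."""


class NumericalError(DyncoreError, ArithmeticError):
    """Numerical failure, e.g. non-finite estimate (CLI exit code 4)."""


class DegenerateDataError(DyncoreError, ValueError):
    """Input data is degenerate for the requested statistic (exit code 3)."""
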