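"""Exception hierarchy shared across the package.

``DataError`` subclasses ``ValueError`` so that sklearn-style input validation
failures behave like ordinary validation errors; the CLI maps each class to a
distinct exit code.
"""


class MultiLinkError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MultiLinkError):
    """Malformed or inconsistent run configuration."""


class DataError(MultiLinkError, ValueError):
    """Invalid input data: parse failures, dimension mismatches, degenerate cohorts."""


class NumericalError(MultiLinkError, ArithmeticError):
    """Numerical failure inside a solver."""
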