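"""Exception hierarchy.

``ConfigError`` signals a misconfiguration (bad column map, inverted bounds);
``DataError`` signals data that cannot support the requested computation.
The CLI maps these to exit codes 2 and 1 respectively.
"""


class TwinvarError(Exception):
    """Base class for all package errors."""


class ConfigError(TwinvarError):
    """Invalid configuration: missing columns, inverted bounds, bad scenario."""


class DataError(TwinvarError):
    """Input data cannot support the requested computation."""


class IdentificationError(DataError):
    """The requested model is not identified from the relation groups present."""


class BoundaryError(DataError):
    """A fit or likelihood evaluation hit a degenerate boundary (singular
    expected covariance). Usually means E=0 with a within-pair correlation of
    one was requested; supply a model with a positive unique-environment
    component."""
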