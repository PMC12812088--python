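"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: :class:`InputError` -> 2,
:class:`PreconditionError` -> 3.
"""


class JumpsieveError(Exception):
    """Base class for all package errors."""


class InputError(JumpsieveError):
    """Malformed or inconsistent input data (bad file, duplicate keys, ...)."""


class PreconditionError(JumpsieveError):
    """A method's scientific precondition is not met (e.g. no blank samples,
    too few blank observations to derive a threshold, no outliers)."""
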