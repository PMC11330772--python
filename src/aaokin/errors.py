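"""Exception hierarchy shared by all analysis stages.

The CLI maps these onto exit codes: :class:`InputError` -> 2,
:class:`FitError` -> 3.
"""


class AaokinError(Exception):
    """Base class for all package-specific errors."""


class InputError(AaokinError, ValueError):
    """Malformed, inconsistent or unidentifiable input data."""


class ModelSpecificationError(InputError):
    """A parameter set that does not match the requested rate law."""


class FitError(AaokinError, RuntimeError):
    """Non-convergence or an internally inconsistent fit result."""
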