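"""Exception hierarchy shared by all aromams modules.

Two broad classes matter to callers (and to the CLI exit codes): problems
with input files (:class:`InputError`) and problems with parameters or
configuration (:class:`ParameterError`).
"""


class AromaMSError(Exception):
    """Base class for every error raised by aromams."""


class InputError(AromaMSError):
    """An input file is missing, unreadable, or malformed."""


class EmptyInputError(InputError):
    """An input parsed cleanly but contained no usable records."""


class ParameterError(AromaMSError, ValueError):
    """A parameter or configuration value is out of its valid range."""


class FormulaError(ParameterError):
    """A molecular formula string could not be parsed."""


class CalibrationError(ParameterError):
    """A retention-index calibration cannot be built from the given ladder."""


class SceneError(ParameterError):
    """A synthetic scene is infeasible under the requested constraints."""
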