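"""Exception hierarchy.

``ConfigurationError`` and friends map to exit code 2 on the command line,
``OptimizationError`` to exit code 3.
"""


class JDSNMFError(Exception):
    """Base class for all package errors."""


class ConfigurationError(JDSNMFError, ValueError):
    """Invalid configuration: bad activation name, negative lambda, bad dims."""


class ShapeError(JDSNMFError, ValueError):
    """Factor / data shapes are inconsistent."""


class DegenerateInputError(JDSNMFError, ValueError):
    """Input is degenerate for the requested operation (e.g. constant block)."""


class OptimizationError(JDSNMFError, RuntimeError):
    """Non-finite loss or other numerical failure during fitting."""


class AlignmentError(JDSNMFError, ValueError):
    """Matched-axis identifiers disagree across blocks."""


class ParseError(JDSNMFError, ValueError):
    """A matrix / manifest / covariate file could not be parsed."""


class IntegrityError(JDSNMFError, ValueError):
    """A saved model directory is corrupt or inconsistent with its sidecar."""


class SplitError(JDSNMFError, ValueError):
    """A requested stratified split cannot be formed."""


class DegenerateTestError(JDSNMFError, ValueError):
    """A statistical test is undefined on the given input."""
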