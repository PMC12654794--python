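"""Exception hierarchy for ravmd."""


class RavmdError(Exception):
    """Base class for all ravmd errors."""


class SizeError(RavmdError):
    """Input has too few elements or mismatched shapes."""


class GenerationError(RavmdError):
    """Random structure generation failed within the retry budget."""


class NumericError(RavmdError):
    """Non-finite or out-of-domain numeric input."""


class MappingError(RavmdError):
    """A restraint could not be resolved to sites on the chain."""


class ConfigError(RavmdError):
    """Invalid run configuration or schedule."""


class DegenerateAverageError(NumericError):
    """Circular average undefined (sine and cosine means both vanish)."""


class MinimizationError(RavmdError):
    """Local energy minimization diverged."""


class ParseError(RavmdError):
    """Malformed structure or restraint file."""
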