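"""Exception hierarchy shared across the pipeline."""


class BsaMutfindError(Exception):
    """Base class for all package errors."""


class ValidationError(BsaMutfindError, ValueError):
    """A value violates a domain invariant (e.g. alt depth > total depth)."""


class FormatError(BsaMutfindError, ValueError):
    """An input file does not conform to the expected dialect."""


class ConfigurationError(BsaMutfindError, ValueError):
    """A configuration is internally inconsistent or names unknown entities."""


class SimulationError(BsaMutfindError, RuntimeError):
    """A simulation cannot proceed under the requested parameters."""
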