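"""Exception hierarchy shared across the pipeline."""


class MutscreenError(Exception):
    """Base class for all pipeline errors."""


class FormatError(MutscreenError):
    """A file could not be parsed as the format it claims to be."""


class ValidationError(MutscreenError):
    """Parsed data violates an invariant of the data model."""


class ConfigurationError(MutscreenError):
    """A configuration is internally inconsistent or infeasible."""
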