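"""Exception hierarchy shared across the package."""


class CorephyloError(Exception):
    """Base class for all package errors."""


class ConfigError(CorephyloError):
    """Invalid configuration value; the message names the offending field."""


class ParseError(CorephyloError):
    """Malformed input file; the message names the file, column, or line."""


class PipelineError(CorephyloError):
    """A pipeline stage failed; the message names the stage and the cause."""
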