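"""Exception hierarchy shared across the pipeline stages."""


class AlienscanError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(AlienscanError, ValueError):
    """An invalid simulation or pipeline configuration value."""


class ParameterError(AlienscanError, ValueError):
    """An invalid argument to an individual operation."""


class FastaParseError(AlienscanError, ValueError):
    """Malformed FASTA input; the message names the offending line."""


class DataIntegrityError(AlienscanError, ValueError):
    """Cross-references between stage artifacts do not resolve."""
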