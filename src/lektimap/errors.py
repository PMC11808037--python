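"""Exception hierarchy.

``ValidationError`` covers malformed inputs (bad HGVS, bad cohort rows,
bad configs); ``StatsError`` covers statistical preconditions (constant
outcome, zero contingency margin, empty model table). The CLI maps them
to exit codes 2 and 3 respectively.
"""


class LektimapError(Exception):
    """Base class for package errors."""


class ValidationError(LektimapError):
    """Input does not satisfy the schema or a precondition."""


class HgvsParseError(ValidationError):
    """An HGVS c. string could not be decomposed."""


class ConfigError(ValidationError):
    """A simulation or pipeline configuration is invalid."""


class StatsError(LektimapError):
    """A statistical operation cannot be carried out on the given data."""
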