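"""Exception hierarchy for vfnorm.

Every error raised deliberately by the package derives from :class:`VfnormError`
so callers (and the CLI) can catch one type and exit nonzero with a message.
"""


class VfnormError(Exception):
    """Base class for all vfnorm errors."""


class UnsupportedPatternError(VfnormError):
    """A test-pattern identifier is not one of the supported grids."""


class MalformedRecordError(VfnormError):
    """A visual-field test record is inconsistent with its pattern."""


class MissingDataError(VfnormError):
    """A required field is absent; eligibility is never silently passed."""


class InsufficientDataError(VfnormError):
    """Too few observations to fit or summarize."""


class ModelIntegrityError(VfnormError):
    """A normative model violates its internal invariants."""


class ConfigError(VfnormError):
    """A configuration value is out of its allowed range."""


class SchemaError(VfnormError):
    """A file does not conform to its documented schema."""
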