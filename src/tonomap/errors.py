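"""Exception hierarchy.

Everything user-facing derives from :class:`TonomapError` so the CLI can map
validation/integrity failures to exit code 2 without catching bare exceptions.
"""


class TonomapError(ValueError):
    """Base class for all tonomap errors."""


class ValidationError(TonomapError):
    """A parameter or configuration value violates its contract."""


class IntegrityError(TonomapError):
    """A dataset on disk is internally inconsistent."""
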