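"""Exception hierarchy for mrscore.

All errors raised on bad user input derive from :class:`MrscoreError` so
callers (and the CLI) can catch one base class.
"""


class MrscoreError(Exception):
    """Base class for all mrscore errors."""


class SchemaError(MrscoreError):
    """A summary-statistics file does not match the expected schema."""


class ValidationError(MrscoreError):
    """A record violates a domain invariant (bounds, duplicates, alleles)."""


class HarmonizationError(MrscoreError):
    """Exposure and outcome records cannot be expressed on a common allele."""


class WeakInstrumentError(MrscoreError):
    """The exposure effect is zero, so the Wald ratio is undefined."""


class LdUndefinedError(MrscoreError):
    """LD is undefined because at least one locus is monomorphic."""


class MissingLdError(MrscoreError):
    """No LD record is available for a variant that needs one."""


class PipelineError(MrscoreError):
    """A pipeline stage failed; the message names the stage and offender."""
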