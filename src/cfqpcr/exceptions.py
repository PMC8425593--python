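"""Exception hierarchy for the cfqpcr pipeline."""


class CfqpcrError(Exception):
    """Base class for all package errors."""


class FormatError(CfqpcrError):
    """A file does not have the declared tabular schema."""


class ValidationError(CfqpcrError):
    """Parsed data violates a table invariant (duplicates, bad ranges, ...)."""


class ConfigurationError(CfqpcrError):
    """A simulation or analysis configuration field is invalid."""


class NormalizationError(CfqpcrError):
    """Reference-based normalization cannot proceed (no usable spike-in, empty cohort)."""


class NoPeakError(CfqpcrError):
    """A melt curve has no dynamic range, so no peak temperature exists."""


class UnclassifiableError(CfqpcrError):
    """A clinical snapshot carries no usable field for response classification."""
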