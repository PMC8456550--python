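"""Exception types shared across the pipeline."""


class TransmutError(Exception):
    """Base class for all package errors."""


class DataError(TransmutError):
    """Input data violates a precondition (e.g. ref allele mismatch)."""


class ConfigurationError(TransmutError):
    """Invalid configuration or parameter value."""


class VcfParseError(DataError):
    """A VCF record could not be parsed."""


class UndefinedTestError(DataError):
    """A contingency table has a zero margin, so the test is undefined."""
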