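"""Exception hierarchy for the pipeline."""


class CryptVillusError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CryptVillusError):
    """An invalid configuration value; the message names the field."""


class InputError(CryptVillusError):
    """Malformed or out-of-domain input data."""


class QuantificationError(CryptVillusError):
    """A relative-quantification step is missing a required term."""


class NormalizationError(CryptVillusError):
    """Normalization cannot proceed (e.g. empty common-assay set)."""
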