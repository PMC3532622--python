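"""Exception types shared across the package."""


class MsiSigError(ValueError):
    """Base class for all msisig errors."""


class FormatError(MsiSigError):
    """A file could not be parsed into the expected tabular layout."""


class ValidationError(MsiSigError):
    """Parsed data violate a domain-type invariant."""
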