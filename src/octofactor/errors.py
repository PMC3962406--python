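"""Exception hierarchy shared across the package."""


class OctofactorError(Exception):
    """Base class for all package-specific errors."""


class FormatError(OctofactorError, ValueError):
    """A file does not conform to the expected on-disk layout."""


class ValidationError(OctofactorError, ValueError):
    """Parsed content violates a domain invariant (e.g. duplicate accession)."""


class ContractError(OctofactorError, ValueError):
    """An operation was called with arguments violating its preconditions."""
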