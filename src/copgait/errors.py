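"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when input data violate a documented invariant.

    Carries enough context (row numbers, identifiers) to locate the
    offending record; validation never silently repairs data.
    """


class UsageError(Exception):
    """Raised for malformed configuration or command-line usage."""
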