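"""Exception types shared across the package."""


class LandracekitError(Exception):
    """Base class for all landracekit errors."""


class FormatError(LandracekitError, ValueError):
    """A file or table does not have the expected on-disk layout."""


class ValidationError(LandracekitError, ValueError):
    """Data parsed correctly but violates a domain invariant."""
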