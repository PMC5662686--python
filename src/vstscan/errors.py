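"""Exception hierarchy shared across the package."""


class VstScanError(Exception):
    """Base class for all vstscan errors."""


class ParseError(VstScanError):
    """A file could not be parsed; the message names the offending location."""


class ValidationError(VstScanError):
    """An in-memory object violates a domain invariant."""
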