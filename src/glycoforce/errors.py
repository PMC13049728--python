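"""Exception hierarchy."""


class GlycoforceError(Exception):
    """Base class for all package errors."""


class CurveParseError(GlycoforceError):
    """A curve or map file violates the documented dialect."""


class InvariantError(GlycoforceError):
    """A domain object failed its construction invariants."""


class NoContactError(GlycoforceError):
    """No force rise detected on an approach curve."""


class FitError(GlycoforceError):
    """A fit could not be set up (too few points, bad window, ...)."""
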