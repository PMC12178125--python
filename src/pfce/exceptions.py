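"""Exception hierarchy shared across the package."""


class PFCEError(Exception):
    """Base class for all package-specific errors."""


class DataError(PFCEError, ValueError):
    """Malformed, missing, or out-of-domain input data."""


class StructureError(PFCEError, ValueError):
    """Mismatched labels, shapes, or hierarchy structure."""


class SchemeError(PFCEError, ValueError):
    """Invalid grade-threshold scheme."""


class ConsistencyError(PFCEError, RuntimeError):
    """A judgment matrix failed the CR < 0.1 consistency gate."""


class FitError(PFCEError, ValueError):
    """Response-surface regression could not be fitted."""
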