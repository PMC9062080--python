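"""Exception hierarchy for mosaic-hic."""


class MosaicError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MosaicError, ValueError):
    """Malformed input file (wrong shape, asymmetry, bad line)."""


class ResourceError(MosaicError, LookupError):
    """Requested chromosome/resolution/file not available."""


class DegenerateInputError(MosaicError, ValueError):
    """Input is structurally valid but degenerate (e.g. all bins masked)."""


class ParameterError(MosaicError, ValueError):
    """Infeasible or inconsistent parameter combination."""
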