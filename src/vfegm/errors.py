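"""Exception hierarchy shared across the package."""


class VFEGMError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(VFEGMError, ValueError):
    """A configuration or data object violates its invariants."""


class ParseError(VFEGMError, ValueError):
    """An ASCII electrogram file could not be parsed.

    The message always names the offending line number.
    """


class DegenerateSignalError(VFEGMError, ValueError):
    """A signal is constant, silent or otherwise carries no usable variation."""


class NoHarmonicStructureError(VFEGMError, ValueError):
    """No spectral peaks were found in the analysis band."""


class DegenerateTestError(VFEGMError, ValueError):
    """A paired test cannot be computed (zero-variance differences)."""


class PipelineError(VFEGMError, RuntimeError):
    """A pipeline stage failed; the message carries stage and patient tags."""
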