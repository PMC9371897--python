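"""Exception types shared across the package."""


class NickLatticeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NickLatticeError):
    """A design, mask or motif configuration is invalid or inconsistent."""


class CapacityError(NickLatticeError):
    """A requested exact computation exceeds the supported problem size."""


class FitError(NickLatticeError):
    """A curve fit failed to converge or its inputs are unusable."""


class TmUndefinedError(FitError):
    """The fitted survival curve never crosses 0.5, so Tm is undefined."""
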