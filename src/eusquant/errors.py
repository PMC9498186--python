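"""Exception hierarchy shared across the package."""


class EusquantError(Exception):
    """Base class for all package-specific errors."""


class InputError(EusquantError, ValueError):
    """A caller-supplied argument or file is unusable."""


class ValidationError(InputError):
    """An annotation or derived object violates a documented invariant."""


class ImageFormatError(InputError):
    """The image cannot be represented as 8-bit grayscale."""


class EmptyRegionError(EusquantError, ValueError):
    """A metric was requested for a region with no member pixels."""


class UndefinedSDError(EusquantError, ValueError):
    """Standard deviation requested for a region with fewer than 2 pixels."""


class InconsistentRegionsError(EusquantError, ValueError):
    """Moment subtraction of a region that is not a subset of its parent."""


class FullyCysticError(EusquantError, ValueError):
    """The cystic part covers the whole lesion; solid metrics are undefined."""


class DegenerateSampleError(EusquantError, ValueError):
    """A statistical test was asked to run on a constant (zero-variance) sample."""
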