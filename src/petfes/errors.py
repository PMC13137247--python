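"""Exception hierarchy shared across the package."""


class PetfesError(Exception):
    """Base class for all package-specific errors."""


class InvalidAngleError(PetfesError, ValueError):
    """A torsion angle is non-finite or outside (-180, 180]."""


class NoDataError(PetfesError, ValueError):
    """An operation received an empty trajectory or region."""


class InvalidRestraintError(PetfesError, ValueError):
    """A wall restraint has a negative force constant or bad exponent."""


class InvalidGeometryError(PetfesError, ValueError):
    """A chain geometry violates its invariants."""


class SamplerError(PetfesError, RuntimeError):
    """The Monte Carlo sampler failed (e.g. stuck acceptance)."""


class UnreachableRatioError(PetfesError, ValueError):
    """A target conformer ratio cannot be produced by any finite gap."""


class ColvarFormatError(PetfesError, ValueError):
    """A COLVAR-dialect table is malformed."""


class ConfigError(PetfesError, ValueError):
    """A run configuration contains unknown or invalid keys."""
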