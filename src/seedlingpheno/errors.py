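"""Exception hierarchy for the phenotyping pipeline."""


class PhenotypeError(Exception):
    """Base class for all errors raised by this package."""


class EmptyCloudError(PhenotypeError):
    """An operation received (or would produce) a cloud with no points."""


class InvalidIntrinsicsError(PhenotypeError):
    """Camera intrinsics violate their invariants (e.g. non-positive focal length)."""


class CloudIOError(PhenotypeError):
    """Malformed point-cloud file, unknown extension, or mismatched counts."""


class DegenerateHullError(PhenotypeError):
    """Fewer than three points, or all points collinear: no 2D convex hull."""


class InsufficientPointsError(PhenotypeError):
    """Too few points for the requested fit or estimate."""


class EllipseFitError(PhenotypeError):
    """Direct ellipse fit failed (degenerate conic)."""


class MissingIntensityError(PhenotypeError):
    """A grayscale-based step was applied to a cloud without intensities."""


class EmptyPlantError(PhenotypeError):
    """No plant points remain above the soil plane."""


class EmptyStemError(PhenotypeError):
    """Canopy removal discarded the entire skeleton path."""


class ShortPathError(PhenotypeError):
    """The skeleton path is too short for the requested operation."""


class BelowSoilError(PhenotypeError):
    """Plant height would be non-positive (all points at or below the soil)."""


class SingularFitError(PhenotypeError):
    """Least-squares fit is underdetermined (e.g. all densities equal)."""


class ZeroVarianceError(PhenotypeError):
    """Pearson correlation undefined: one of the paired vectors is constant."""


class InfeasibleSpecError(PhenotypeError):
    """A synthetic plant specification is geometrically infeasible."""


class ConfigError(PhenotypeError):
    """Invalid pipeline configuration (unknown key or out-of-range value)."""


class StageError(PhenotypeError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage '{stage}' failed: {original!r}")
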