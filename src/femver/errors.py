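"""Exception and warning types shared across the package."""


class FemverError(Exception):
    """Base class for all package-specific errors."""


class DegenerateGeometryError(FemverError):
    """Input geometry does not determine the requested primitive
    (collinear circle points, coincident landmarks, ...)."""


class InsufficientGeometryError(FemverError):
    """Not enough valid geometry to run the fit (e.g. too few shaft slices)."""


class MissingLandmarkError(FemverError):
    """A named landmark or face label required by the operation is absent."""


class UndefinedProjectionError(FemverError):
    """A direction is (numerically) parallel to the projection axis."""


class OrientationError(FemverError):
    """Landmarks are ordered inconsistently along the anatomical axis."""


class RegistrationError(FemverError):
    """Surface registration cannot be performed (e.g. empty point sets)."""


class MissingStructureError(FemverError):
    """A measured structure (calcar femorale) is absent from the record."""


class IncompleteRecordError(FemverError):
    """A morphometry record lacks a field required by the statistical stage."""


class SpecError(FemverError, ValueError):
    """A generator spec is internally inconsistent."""


class SchemaError(FemverError):
    """A table is missing required columns or has malformed values."""


class UnstableMeasurementWarning(UserWarning):
    """Measurement is defined but numerically unstable (near-circular section,
    tied Feret diameters); the returned value should be treated with caution."""


class NonConvergenceWarning(UserWarning):
    """Iterative procedure hit its iteration cap before the tolerance."""
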