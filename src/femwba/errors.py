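"""Exception hierarchy.

Every error raised by the package derives from :class:`FemwbaError` so callers
(and the CLI) can distinguish configuration problems from computation failures.
"""


class FemwbaError(Exception):
    """Base class for all package errors."""


class ParameterError(FemwbaError, ValueError):
    """An input parameter violates its documented invariant."""


class ConfigError(FemwbaError, ValueError):
    """A pipeline configuration is inconsistent or references missing files."""


class MissingLandmarkError(FemwbaError, KeyError):
    """A required named landmark is absent from the landmark set."""

    def __init__(self, name: str):
        self.landmark = name
        super().__init__(f"required landmark {name!r} is missing")


class DegenerateGeometryError(FemwbaError, ValueError):
    """Coincident points / near-zero angles make a construction ill-defined."""


class RegistrationError(FemwbaError, ValueError):
    """Landmark registration cannot be computed (too few or degenerate points)."""


class MeshingError(FemwbaError, ValueError):
    """Tetrahedral or surface meshing failed."""


class FitFailureError(FemwbaError, ValueError):
    """Sphere fit did not converge to an acceptable residual."""


class EmptyPatchError(FemwbaError, ValueError):
    """A trimming constraint removed every facet."""

    def __init__(self, constraint: str):
        self.constraint = constraint
        super().__init__(f"trimming constraint {constraint!r} removed all facets")


class SolverError(FemwbaError, RuntimeError):
    """The finite-element system is singular or an element is invalid."""
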