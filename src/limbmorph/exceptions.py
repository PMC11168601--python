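"""Exception hierarchy for limbmorph."""


class LimbmorphError(Exception):
    """Base class for all limbmorph errors."""


class MeshValidationError(LimbmorphError):
    """A mesh violates a structural invariant (bad face index, NaN vertex...)."""


class STLFormatError(LimbmorphError):
    """A surface file could not be parsed as STL/PLY."""


class LandmarkError(LimbmorphError):
    """Landmark pairs are missing, too few, or degenerate."""


class RegistrationError(LimbmorphError):
    """Rigid registration could not proceed (no correspondences, degenerate fit)."""


class OrientationError(LimbmorphError):
    """A surface's vertex normals are too ill-defined for signed comparison."""


class PhantomError(LimbmorphError):
    """Phantom specification invalid or deformation drives skin into bone."""
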