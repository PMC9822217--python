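"""Exception hierarchy.

Every error raised by the package derives from :class:`BonemapError` and
carries a short machine-parsable ``code`` used by the CLI exit path.
"""


class BonemapError(Exception):
    """Base class for all package errors."""

    code = "error"


class VolumeReadError(BonemapError):
    """CT volume could not be read or its metadata is inconsistent."""

    code = "volume-read"


class OutOfBoundsError(BonemapError):
    """A world coordinate fell outside the voxel-center hull in strict mode."""

    code = "out-of-bounds"


class MeshError(BonemapError):
    code = "mesh"


class UnsupportedElementError(MeshError):
    """Element type other than the supported 4-node tetrahedron."""

    code = "unsupported-element"


class DegenerateElementError(MeshError):
    """Tetrahedron with volume below the degeneracy tolerance."""

    code = "degenerate-element"


class LawChainError(BonemapError):
    """Invalid density-modulus law-chain configuration."""

    code = "law-chain"


class MappingError(BonemapError):
    code = "mapping"


class BinningError(BonemapError):
    code = "binning"


class SolverError(BonemapError):
    """Singular or ill-posed verification solve."""

    code = "solver"


class ConfigError(BonemapError):
    code = "config"
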