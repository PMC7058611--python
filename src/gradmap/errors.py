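"""Named exception types raised across the package.

Every user-facing failure mode has its own class so callers (and the CLI)
can report the precise contract that was violated instead of a generic
ValueError.
"""


class GradmapError(Exception):
    """Base class for all package errors."""


# --- I/O -----------------------------------------------------------------

class MissingFileError(GradmapError, FileNotFoundError):
    """Input path does not exist."""


class RaggedRowsError(GradmapError):
    """Delimited matrix rows have inconsistent lengths."""


class NonNumericError(GradmapError):
    """A cell could not be parsed as a number."""


class NonFiniteError(GradmapError):
    """NaN or Inf encountered where finite values are required."""


class EmptyFileError(GradmapError):
    """File contains no data rows."""


class MeshFormatError(GradmapError):
    """Mesh file is malformed or not in the declared format."""


class FaceIndexError(GradmapError):
    """A face references a vertex index outside [0, n_vertices)."""


class LabelError(GradmapError):
    """Parcellation labels are invalid (non-integer, or degenerate)."""


# --- affinity ------------------------------------------------------------

class SparsityError(GradmapError):
    """Sparsity / keep-fraction parameter outside its valid range."""


class ZeroNormRowError(GradmapError):
    """A row has zero L2 norm; angle-based kernels are undefined."""


class ZeroVarianceRowError(GradmapError):
    """A row is constant; correlation kernels are undefined."""


class PrecomputedAffinityError(GradmapError):
    """Precomputed affinity input is not square symmetric."""


class NegativeAffinityError(GradmapError):
    """Affinity matrix contains negative entries where non-negativity is required."""


# --- embedding -----------------------------------------------------------

class DisconnectedGraphError(GradmapError):
    """Affinity graph has more than one connected component."""


class ZeroDegreeError(GradmapError):
    """A node has zero degree (empty row) in the affinity matrix."""


class ConstantInputError(GradmapError):
    """Input matrix is constant; the decomposition is degenerate."""


class ComponentCountError(GradmapError):
    """Requested number of components exceeds what the input supports."""


# --- alignment -----------------------------------------------------------

class ShapeMismatchError(GradmapError):
    """Gradient sets (or feature matrices) have incompatible shapes."""


class FeatureMismatchError(GradmapError):
    """Joint embedding requires all input matrices to share the same features
    (identical number of columns)."""


# --- mesh / nulls --------------------------------------------------------

class CoincidentVerticesError(GradmapError):
    """Neighboring mesh vertices coincide; inverse-distance weight undefined."""


class NotSphericalError(GradmapError):
    """Mesh vertices do not lie on a common sphere."""


class SingletonCapacityError(GradmapError):
    """Requested more singleton randomizations than the 2^(l-1) unique
    sign assignments available."""


class ConstantMapError(GradmapError):
    """Scalar map is constant; autocorrelation statistics are undefined."""
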