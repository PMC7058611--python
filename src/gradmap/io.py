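"""Core data containers and file I/O.

The containers here are shared by every other module: feature matrices
(seed-by-feature data such as connectivity rows), affinity matrices,
triangle and sphere meshes, vertex-wise scalar maps, and parcellation
label vectors.

File formats supported: delimited text (comma or tab), MatrixMarket,
ASCII PLY, and GIFTI (.surf.gii / .func.gii / .label.gii). All face
indices are 0-based internally; converters at the I/O boundary handle
each format's own convention. Delimited numbers are written with 17
significant digits so that doubles round-trip exactly.

NaN in any input file is an error, never an implicit mask: masking is
explicit via :attr:`ScalarMap.mask`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.io
import scipy.sparse

from . import errors

__all__ = [
    "FeatureMatrix",
    "AffinityMatrix",
    "TriangleMesh",
    "SphereMesh",
    "ScalarMap",
    "ParcellationLabels",
    "read_matrix",
    "write_matrix",
    "read_mesh",
    "write_mesh",
    "read_scalar_map",
    "write_scalar_map",
    "read_labels",
    "write_labels",
]

# Numbers are emitted with 17 significant digits: the smallest count that
# guarantees binary64 -> decimal -> binary64 round-trips bit-identically.
_FLOAT_FMT = "%.17g"


@dataclass
class FeatureMatrix:
    """An n-by-p matrix of p features for each of n seed regions.

    Rows are seeds (e.g., cortical locations), columns are features
    (e.g., connectivity targets). Entries must be finite and both
    dimensions at least 2.
    """

    values: np.ndarray
    row_ids: Optional[Sequence[str]] = None
    col_ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise errors.ShapeMismatchError(
                f"feature matrix must be 2-D, got shape {self.values.shape}"
            )
        n, p = self.values.shape
        if n < 2 or p < 2:
            raise errors.ShapeMismatchError(
                f"feature matrix needs n >= 2 and p >= 2, got {n}x{p}"
            )
        if not np.all(np.isfinite(self.values)):
            raise errors.NonFiniteError("feature matrix contains NaN or Inf")

    @property
    def n_seeds(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class AffinityMatrix:
    """Symmetric non-negative n-by-n similarity matrix fed to embeddings."""

    values: np.ndarray
    kernel_name: str = "precomputed"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        A = self.values
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise errors.ShapeMismatchError(
                f"affinity matrix must be square, got shape {A.shape}"
            )
        if not np.all(np.isfinite(A)):
            raise errors.NonFiniteError("affinity matrix contains NaN or Inf")
        scale = np.abs(A).max()
        tol = 1e-10 * (scale if scale > 0 else 1.0)
        if np.abs(A - A.T).max() > tol:
            raise errors.ShapeMismatchError(
                "affinity matrix is not symmetric within 1e-10 relative tolerance"
            )
        if A.min() < 0:
            raise errors.NegativeAffinityError(
                f"affinity matrix has negative entries (min {A.min():g})"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class TriangleMesh:
    """Triangle surface mesh: l-by-3 vertex coordinates, t-by-3 faces.

    Face indices are 0-based. Degenerate faces (repeated vertex index)
    are rejected.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise errors.MeshFormatError(
                f"vertices must be l x 3, got {self.vertices.shape}"
            )
        if self.vertices.shape[0] < 4:
            raise errors.MeshFormatError("mesh needs at least 4 vertices")
        if not np.all(np.isfinite(self.vertices)):
            raise errors.NonFiniteError("mesh vertices contain NaN or Inf")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise errors.MeshFormatError(f"faces must be t x 3, got {self.faces.shape}")
        l = self.vertices.shape[0]
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= l):
            bad = self.faces.max() if self.faces.max() >= l else self.faces.min()
            raise errors.FaceIndexError(
                f"face index {bad} outside [0, {l}) for {l}-vertex mesh"
            )
        f = self.faces
        if f.size and np.any(
            (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        ):
            raise errors.MeshFormatError("mesh contains degenerate faces")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]


@dataclass
class SphereMesh(TriangleMesh):
    """Triangle mesh whose vertices lie on a common sphere.

    Used for spin permutations, which rotate data on a spherical surface
    registration. The common radius is checked to 1e-6 relative.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        norms = np.linalg.norm(self.vertices, axis=1)
        radius = norms.mean()
        if radius <= 0 or np.abs(norms - radius).max() > 1e-6 * radius:
            raise errors.NotSphericalError(
                "vertices do not lie on a common sphere within 1e-6 relative"
            )

    @property
    def radius(self) -> float:
        return float(np.linalg.norm(self.vertices, axis=1).mean())


@dataclass
class ScalarMap:
    """One scalar value per mesh vertex, with an optional exclusion mask.

    ``mask[i] = True`` marks vertex i as excluded from analysis (e.g.,
    the medial wall); all statistics in this package skip masked
    vertices. Values themselves must be finite everywhere — NaN in an
    input file is rejected rather than treated as an implicit mask.
    """

    values: np.ndarray
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise errors.NonFiniteError("scalar map contains NaN or Inf")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool).ravel()
            if self.mask.shape != self.values.shape:
                raise errors.ShapeMismatchError(
                    "mask length does not match scalar map length"
                )

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def included(self) -> np.ndarray:
        """Boolean vector of vertices that participate in analysis."""
        if self.mask is None:
            return np.ones(len(self), dtype=bool)
        return ~self.mask


@dataclass
class ParcellationLabels:
    """Integer parcel label per vertex; ``background_label`` marks vertices
    outside every parcel."""

    labels: np.ndarray
    background_label: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64).ravel()
        distinct = np.unique(self.labels)
        fg = distinct[distinct != self.background_label]
        if fg.size < 2:
            raise errors.LabelError(
                "parcellation needs at least 2 distinct non-background labels"
            )

    @property
    def parcel_ids(self) -> np.ndarray:
        """Sorted non-background labels."""
        ids = np.unique(self.labels)
        return ids[ids != self.background_label]

    def __len__(self) -> int:
        return self.labels.shape[0]


# ---------------------------------------------------------------------------
# matrices


def _detect_delimiter(line: str) -> str:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return None  # whitespace


def _parse_delimited(path: str) -> np.ndarray:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise errors.EmptyFileError(f"no data rows in {path}")
    delim = _detect_delimiter(lines[0])
    rows = []
    width = None
    for i, ln in enumerate(lines):
        cells = ln.split(delim) if delim else ln.split()
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise errors.RaggedRowsError(
                f"row {i} has {len(cells)} cells, expected {width} ({path})"
            )
        row = []
        for j, cell in enumerate(cells):
            try:
                val = float(cell)
            except ValueError:
                raise errors.NonNumericError(
                    f"cell ({i},{j}) = {cell!r} is not numeric ({path})"
                ) from None
            row.append(val)
        rows.append(row)
    out = np.array(rows, dtype=float)
    if not np.all(np.isfinite(out)):
        raise errors.NonFiniteError(f"matrix in {path} contains NaN or Inf")
    return out


def read_matrix(path: str, format: str = None) -> FeatureMatrix:
    """Read a feature matrix from delimited text or MatrixMarket.

    ``format`` is ``"delimited"`` or ``"matrix-market"``; when omitted it
    is inferred from the extension (``.mtx`` means MatrixMarket).
    Delimited files auto-detect comma vs. tab vs. whitespace.
    """
    if not os.path.exists(path):
        raise errors.MissingFileError(path)
    if format is None:
        format = "matrix-market" if str(path).endswith(".mtx") else "delimited"
    if format == "matrix-market":
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:
            raise errors.NonNumericError(f"cannot parse MatrixMarket {path}: {exc}")
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        if not np.all(np.isfinite(mat)):
            raise errors.NonFiniteError(f"matrix in {path} contains NaN or Inf")
        return FeatureMatrix(mat)
    if format == "delimited":
        return FeatureMatrix(_parse_delimited(path))
    raise ValueError(f"unknown matrix format {format!r}")


def write_matrix(X, path: str, format: str = None, delimiter: str = ",") -> None:
    """Write a matrix as delimited text (17 significant digits) or MatrixMarket."""
    values = X.values if hasattr(X, "values") else np.asarray(X, dtype=float)
    if format is None:
        format = "matrix-market" if str(path).endswith(".mtx") else "delimited"
    if format == "matrix-market":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(values))
        return
    np.savetxt(path, np.atleast_2d(values), fmt=_FLOAT_FMT, delimiter=delimiter)


# ---------------------------------------------------------------------------
# meshes


def _read_ply_ascii(path: str) -> tuple[np.ndarray, np.ndarray]:
    """Minimal ASCII PLY reader for vertex/face elements.

    Parses the header directly so malformed headers and out-of-range
    face indices raise the package's named errors with a useful message.
    """
    with open(path) as fh:
        magic = fh.readline().strip()
        if magic != "ply":
            raise errors.MeshFormatError(f"{path}: missing 'ply' magic")
        n_vertex = n_face = None
        elements = []  # (name, count) in declaration order
        vertex_props = []
        current = None
        while True:
            line = fh.readline()
            if not line:
                raise errors.MeshFormatError(f"{path}: header ends without end_header")
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "format":
                if tok[1] != "ascii":
                    raise errors.MeshFormatError(f"{path}: only ASCII PLY supported")
            elif tok[0] == "element":
                current = tok[1]
                try:
                    count = int(tok[2])
                except (IndexError, ValueError):
                    raise errors.MeshFormatError(f"{path}: bad element line {line!r}")
                elements.append((tok[1], count))
                if tok[1] == "vertex":
                    n_vertex = count
                elif tok[1] == "face":
                    n_face = count
            elif tok[0] == "property" and current == "vertex" and tok[1] != "list":
                vertex_props.append(tok[2])
            elif tok[0] == "end_header":
                break
        if n_vertex is None or n_face is None:
            raise errors.MeshFormatError(f"{path}: missing vertex or face element")
        try:
            ix, iy, iz = (vertex_props.index(c) for c in "xyz")
        except ValueError:
            raise errors.MeshFormatError(f"{path}: vertex element lacks x/y/z")
        verts = np.empty((n_vertex, 3), dtype=float)
        faces = np.empty((n_face, 3), dtype=np.int64)
        for name, count in elements:
            for i in range(count):
                tok = fh.readline().split()
                if not tok:
                    raise errors.MeshFormatError(f"{path}: truncated {name} data")
                if name == "vertex":
                    try:
                        verts[i] = [float(tok[ix]), float(tok[iy]), float(tok[iz])]
                    except (ValueError, IndexError):
                        raise errors.MeshFormatError(f"{path}: bad vertex row {i}")
                elif name == "face":
                    try:
                        k = int(tok[0])
                        idx = [int(t) for t in tok[1 : 1 + k]]
                    except (ValueError, IndexError):
                        raise errors.MeshFormatError(f"{path}: bad face row {i}")
                    if k != 3:
                        raise errors.MeshFormatError(
                            f"{path}: face {i} has {k} vertices; only triangles supported"
                        )
                    faces[i] = idx
    return verts, faces


def read_mesh(path: str, format: str = None, sphere: bool = False):
    """Read a triangle mesh from ASCII PLY or GIFTI.

    ``format`` is ``"ply-ascii"`` or ``"gifti"``; inferred from the
    extension when omitted. With ``sphere=True`` the result is a
    :class:`SphereMesh` and the common-radius invariant is enforced.
    """
    if not os.path.exists(path):
        raise errors.MissingFileError(path)
    if format is None:
        format = "gifti" if str(path).endswith(".gii") else "ply-ascii"
    if format == "ply-ascii":
        verts, faces = _read_ply_ascii(path)
    elif format == "gifti":
        import nibabel as nib

        img = nib.load(path)
        verts = faces = None
        for da in img.darrays:
            if da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
                verts = np.asarray(da.data, dtype=float)
            elif da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
                faces = np.asarray(da.data, dtype=np.int64)
        if verts is None or faces is None:
            raise errors.MeshFormatError(
                f"{path}: GIFTI lacks POINTSET or TRIANGLE data array"
            )
    else:
        raise ValueError(f"unknown mesh format {format!r}")
    cls = SphereMesh if sphere else TriangleMesh
    return cls(vertices=verts, faces=faces)


def write_mesh(mesh: TriangleMesh, path: str, format: str = None) -> None:
    """Write a triangle mesh as ASCII PLY or GIFTI."""
    if format is None:
        format = "gifti" if str(path).endswith(".gii") else "ply-ascii"
    if format == "ply-ascii":
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {mesh.n_vertices}\n")
            fh.write("property double x\nproperty double y\nproperty double z\n")
            fh.write(f"element face {mesh.n_faces}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            for v in mesh.vertices:
                fh.write(" ".join(_FLOAT_FMT % c for c in v) + "\n")
            for f in mesh.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    elif format == "gifti":
        import nibabel as nib

        img = nib.gifti.GiftiImage(
            darrays=[
                nib.gifti.GiftiDataArray(
                    mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
                ),
                nib.gifti.GiftiDataArray(
                    mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
                ),
            ]
        )
        nib.save(img, path)
    else:
        raise ValueError(f"unknown mesh format {format!r}")


# ---------------------------------------------------------------------------
# scalar maps and labels


def read_scalar_map(path: str) -> ScalarMap:
    """Read a vertex-wise scalar map: one value per line (or GIFTI func)."""
    if not os.path.exists(path):
        raise errors.MissingFileError(path)
    if str(path).endswith(".gii"):
        import nibabel as nib

        img = nib.load(path)
        vals = np.asarray(img.darrays[0].data, dtype=float).ravel()
        if not np.all(np.isfinite(vals)):
            raise errors.NonFiniteError(f"scalar map in {path} contains NaN or Inf")
        return ScalarMap(vals)
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise errors.EmptyFileError(f"no data in {path}")
    vals = []
    for i, ln in enumerate(lines):
        cell = ln.split()[0].split(",")[0]
        try:
            v = float(cell)
        except ValueError:
            raise errors.NonNumericError(f"line {i} = {cell!r} is not numeric") from None
        if not np.isfinite(v):
            raise errors.NonFiniteError(f"line {i} of {path} is NaN/Inf")
        vals.append(v)
    return ScalarMap(np.array(vals))


def write_scalar_map(data, path: str) -> None:
    values = data.values if hasattr(data, "values") else np.asarray(data, dtype=float)
    np.savetxt(path, np.asarray(values).ravel(), fmt=_FLOAT_FMT)


def read_labels(path: str, background_label: int = 0) -> ParcellationLabels:
    """Read integer parcellation labels, one per line; non-integers rejected."""
    if not os.path.exists(path):
        raise errors.MissingFileError(path)
    if str(path).endswith(".gii"):
        import nibabel as nib

        img = nib.load(path)
        arr = np.asarray(img.darrays[0].data)
        if not np.all(arr == np.round(arr)):
            raise errors.LabelError(f"{path}: non-integer labels")
        return ParcellationLabels(arr.astype(np.int64), background_label)
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise errors.EmptyFileError(f"no data in {path}")
    labels = []
    for i, ln in enumerate(lines):
        cell = ln.split()[0].split(",")[0]
        try:
            v = float(cell)
        except ValueError:
            raise errors.LabelError(f"line {i} = {cell!r} is not a label") from None
        if v != int(v):
            raise errors.LabelError(f"line {i} = {cell!r} is not an integer label")
        labels.append(int(v))
    return ParcellationLabels(np.array(labels, dtype=np.int64), background_label)


def write_labels(labels, path: str) -> None:
    arr = labels.labels if hasattr(labels, "labels") else np.asarray(labels)
    arr = np.asarray(arr).ravel().astype(np.int64)
    if str(path).endswith(".gii"):
        import nibabel as nib

        img = nib.gifti.GiftiImage(
            darrays=[
                nib.gifti.GiftiDataArray(
                    arr.astype(np.int32), intent="NIFTI_INTENT_LABEL"
                )
            ]
        )
        nib.save(img, path)
        return
    np.savetxt(path, arr, fmt="%d")
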