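"""Volume and label-map containers, NIfTI / mesh I/O, resampling and normalization.

The package works on 3D scalar volumes (angiographic and enhancement channels)
and integer label maps sharing a volume's grid.  World coordinates follow one
documented convention throughout:

    world = origin + direction @ (index * spacing)

with 0-based voxel indices, ``index`` ordered like the array axes, spacing in
mm, and ``direction`` a 3x3 orthonormal matrix (identity for the synthetic
phantoms).  The through-plane axis is the third array axis; in-plane
resampling therefore acts on the first two axes only.

Label codes: 0 background, 1 blood pool, 2 veins + appendage, 3 mitral valve.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

LABEL_BACKGROUND = 0
LABEL_BLOOD_POOL = 1
LABEL_VEINS = 2
LABEL_MV = 3
LABEL_CODES = (LABEL_BACKGROUND, LABEL_BLOOD_POOL, LABEL_VEINS, LABEL_MV)


@dataclasses.dataclass
class Volume:
    """A 3D scalar image with grid metadata.

    Parameters
    ----------
    data : (nx, ny, nz) float array
    spacing : (3,) voxel spacing in mm, all components > 0
    origin : (3,) world position of voxel (0, 0, 0) in mm
    direction : (3, 3) orthonormal direction-cosine matrix
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.direction is None:
            self.direction = np.eye(3)
        self.direction = np.asarray(self.direction, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix is not orthonormal")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine."""
        a = np.eye(4)
        a[:3, :3] = self.direction * self.spacing[np.newaxis, :]
        a[:3, 3] = self.origin
        return a

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices (may be fractional) to world mm."""
        idx = np.asarray(idx, dtype=float)
        return idx * self.spacing @ self.direction.T + self.origin

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map (..., 3) world-mm points to fractional voxel indices."""
        pts = np.asarray(pts, dtype=float)
        return (pts - self.origin) @ self.direction / self.spacing

    def copy_with(self, data: np.ndarray) -> "Volume":
        return Volume(data, self.spacing.copy(), self.origin.copy(), self.direction.copy())


@dataclasses.dataclass
class LabelMap(Volume):
    """An integer label image sharing a Volume grid.

    Values are restricted to the 4-code set (0 background, 1 blood pool,
    2 veins+appendage, 3 mitral valve).
    """

    def __post_init__(self):
        super().__post_init__()
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.allclose(self.data, np.round(self.data)):
                raise ValueError("label data must be integral")
            self.data = np.round(self.data).astype(np.int16)
        extra = set(np.unique(self.data)) - set(LABEL_CODES)
        if extra:
            raise ValueError(f"label codes outside {LABEL_CODES}: {sorted(extra)}")

    def copy_with(self, data: np.ndarray) -> "LabelMap":
        return LabelMap(data, self.spacing.copy(), self.origin.copy(), self.direction.copy())

    def mask(self, code: int) -> np.ndarray:
        return self.data == code


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def save_volume(v: Volume, path) -> None:
    """Write a Volume (or LabelMap) as NIfTI, preserving the grid affine."""
    data = v.data
    if isinstance(v, LabelMap):
        data = data.astype(np.int16)
    nib.save(nib.Nifti1Image(np.asarray(data), v.affine), str(path))


def _decompose_affine(affine: np.ndarray):
    m = affine[:3, :3]
    spacing = np.linalg.norm(m, axis=0)
    direction = m / spacing[np.newaxis, :]
    return spacing, affine[:3, 3].copy(), direction


def load_volume(path) -> Volume:
    img = nib.load(str(path))
    spacing, origin, direction = _decompose_affine(img.affine)
    return Volume(np.asarray(img.dataobj, dtype=np.float64), spacing, origin, direction)


def load_labelmap(path) -> LabelMap:
    img = nib.load(str(path))
    spacing, origin, direction = _decompose_affine(img.affine)
    return LabelMap(np.asarray(img.dataobj).astype(np.int16), spacing, origin, direction)


# ---------------------------------------------------------------------------
# Resampling and normalization
# ---------------------------------------------------------------------------

def resample_slicewise(v: Volume, target_spacing=(1.0, 1.0), target_shape=(320, 320)) -> Volume:
    """Resample every in-plane slice to a fixed pixel size and matrix.

    Each 2D slice (first two array axes) is rescaled to ``target_spacing``
    (default 1x1 mm) on a ``target_shape`` (default 320x320) matrix; the
    through-plane axis is untouched.  Intensities are interpolated linearly,
    label maps with nearest neighbour.  The output grid keeps the input
    origin, so features stay at the same world position.

    Raises
    ------
    ValueError
        if the volume has a non-axial slice orientation (in-plane axes must
        map onto world axes) or no slices.
    """
    if v.data.shape[2] < 1:
        raise ValueError("volume has no slices")
    if not np.allclose(np.abs(v.direction), np.eye(3), atol=1e-6):
        raise ValueError("resample_slicewise requires an axial (grid-aligned) orientation")

    target_spacing = np.asarray(target_spacing, dtype=float)
    nx, ny = int(target_shape[0]), int(target_shape[1])
    nz = v.data.shape[2]

    # Output index (i, j) sits at i*target_spacing mm from the origin; map it
    # back to the input fractional index i*target_spacing/spacing.
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    src_i = ii * (target_spacing[0] / v.spacing[0])
    src_j = jj * (target_spacing[1] / v.spacing[1])

    is_label = isinstance(v, LabelMap)
    order = 0 if is_label else 1
    out = np.empty((nx, ny, nz), dtype=float)
    for k in range(nz):
        out[:, :, k] = ndimage.map_coordinates(
            np.asarray(v.data[:, :, k], dtype=float),
            np.stack([src_i, src_j]),
            order=order,
            mode="nearest",  # edge extension: constants stay constant, labels stay in-set
        )
    new_spacing = np.array([target_spacing[0], target_spacing[1], v.spacing[2]])
    if is_label:
        return LabelMap(np.round(out).astype(np.int16), new_spacing, v.origin.copy(), v.direction.copy())
    return Volume(out, new_spacing, v.origin.copy(), v.direction.copy())


def minmax_normalize(v: Volume) -> Volume:
    """Affinely rescale intensities to span [0, 1].

    Raises
    ------
    ValueError
        for a constant volume, where the scaling is undefined.
    """
    lo = float(np.min(v.data))
    hi = float(np.max(v.data))
    if hi == lo:
        raise ValueError("cannot min-max normalize a constant volume")
    return v.copy_with((np.asarray(v.data, dtype=float) - lo) / (hi - lo))


# ---------------------------------------------------------------------------
# Mesh I/O: legacy-ASCII VTK polydata (with per-vertex scalars) and PLY
# ---------------------------------------------------------------------------

def save_mesh_vtk(path, vertices, triangles, point_data: dict | None = None) -> None:
    """Write a triangle mesh as legacy ASCII VTK polydata.

    ``point_data`` maps scalar names to per-vertex float arrays.
    """
    vertices = np.asarray(vertices, dtype=float)
    triangles = np.asarray(triangles, dtype=int)
    lines = [
        "# vtk DataFile Version 3.0",
        "atriaquant surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(vertices)} float",
    ]
    lines += [" ".join(f"{c:.6f}" for c in p) for p in vertices]
    lines.append(f"POLYGONS {len(triangles)} {4 * len(triangles)}")
    lines += ["3 " + " ".join(str(i) for i in t) for t in triangles]
    if point_data:
        lines.append(f"POINT_DATA {len(vertices)}")
        for name, values in point_data.items():
            values = np.asarray(values, dtype=float)
            if len(values) != len(vertices):
                raise ValueError(f"scalar '{name}' length {len(values)} != n vertices")
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{x:.6f}" for x in values]
    Path(path).write_text("\n".join(lines) + "\n")


def load_mesh_vtk(path):
    """Read a legacy ASCII VTK polydata triangle mesh written by save_mesh_vtk.

    Returns (vertices, triangles, point_data dict).
    """
    tokens = Path(path).read_text().split("\n")
    it = iter(tokens)
    vertices = triangles = None
    point_data = {}
    line = next(it, None)
    while line is not None:
        parts = line.split()
        if parts[:1] == ["POINTS"]:
            n = int(parts[1])
            vertices = np.array([next(it).split() for _ in range(n)], dtype=float)
        elif parts[:1] == ["POLYGONS"]:
            n = int(parts[1])
            triangles = np.array([next(it).split()[1:] for _ in range(n)], dtype=int)
        elif parts[:1] == ["SCALARS"]:
            name = parts[1]
            next(it)  # LOOKUP_TABLE line
            point_data[name] = np.array([next(it) for _ in range(len(vertices))], dtype=float)
        line = next(it, None)
    if vertices is None or triangles is None:
        raise ValueError(f"{path} is not a polydata mesh")
    return vertices, triangles, point_data


def save_mesh_ply(path, vertices, triangles) -> None:
    import trimesh

    trimesh.Trimesh(vertices, triangles, process=False).export(str(path), file_type="ply", encoding="ascii")


def load_mesh_ply(path):
    import trimesh

    m = trimesh.load(str(path), file_type="ply", process=False)
    return np.asarray(m.vertices), np.asarray(m.faces)
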