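"""Rigid alignment of the angiographic and enhancement volumes.

The two channels are acquired minutes apart, so a rigid transform (3
rotations + 3 translations about the volume centre) suffices.  Alignment
maximizes normalized mutual information,

    NMI(A, B) = (H(A) + H(B)) / H(A, B),

over the joint intensity histogram of the overlap; NMI is >= 1, symmetric,
and invariant to monotone intensity rescaling up to histogram binning.  The
search is multi-resolution (3 levels, downsampling factor 2, Gaussian
pre-smoothing) with gradient-free Powell refinement at each level.

The found transform maps fixed-frame world points to the moving frame; the
segmentation is transported with nearest-neighbour resampling.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage, optimize

from .io import LabelMap, Volume

DEFAULT_BINS = 64


@dataclasses.dataclass
class RigidTransform:
    """Rigid world->world map: x -> R (x - center) + center + translation.

    Rotation angles are degrees about the x, y, z axes (applied in that
    order); the rotation matrix must be orthonormal with determinant +1.
    """

    rotation_deg: np.ndarray
    translation: np.ndarray
    center: np.ndarray

    def __post_init__(self):
        self.rotation_deg = np.asarray(self.rotation_deg, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        R = self.matrix
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9) or not np.isclose(np.linalg.det(R), 1.0):
            raise ValueError("rotation matrix must be orthonormal with det +1")

    @property
    def matrix(self) -> np.ndarray:
        rx, ry, rz = np.deg2rad(self.rotation_deg)
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return Rz @ Ry @ Rx

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - self.center) @ self.matrix.T + self.center + self.translation

    @property
    def homogeneous(self) -> np.ndarray:
        m = np.eye(4)
        R = self.matrix
        m[:3, :3] = R
        m[:3, 3] = self.center + self.translation - R @ self.center
        return m

    def inverse(self) -> "RigidTransform":
        # numeric inverse keeps the (center, angles) parameterization intact
        R = self.matrix.T
        t = -R @ (self.translation)
        # recover Euler angles from R (Rz Ry Rx convention)
        ry = np.arcsin(-R[2, 0])
        rx = np.arctan2(R[2, 1], R[2, 2])
        rz = np.arctan2(R[1, 0], R[0, 0])
        return RigidTransform(np.rad2deg([rx, ry, rz]), t, self.center.copy())

    def save(self, path) -> None:
        np.savetxt(path, self.homogeneous, header="rigid transform, homogeneous 4x4 (world mm)")

    @classmethod
    def load(cls, path, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        m = np.loadtxt(path)
        return cls.from_matrix(m, center)

    @classmethod
    def from_matrix(cls, m: np.ndarray, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        center = np.asarray(center, dtype=float)
        R = m[:3, :3]
        ry = np.arcsin(np.clip(-R[2, 0], -1, 1))
        rx = np.arctan2(R[2, 1], R[2, 2])
        rz = np.arctan2(R[1, 0], R[0, 0])
        t = m[:3, 3] - center + R @ center
        return cls(np.rad2deg([rx, ry, rz]), t, center)


# ---------------------------------------------------------------------------
# normalized mutual information
# ---------------------------------------------------------------------------

def nmi(a, b, bins: int = DEFAULT_BINS) -> float:
    """Normalized mutual information of two intensity arrays on a shared grid.

    NMI = (H(A) + H(B)) / H(A, B) over the joint histogram; 1 for independent
    images, 2 for a one-to-one intensity mapping.  NaN samples (outside the
    overlap) are excluded.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("arrays must have identical shape")
    valid = np.isfinite(a) & np.isfinite(b)
    if valid.sum() == 0:
        raise ValueError("no overlapping field of view")
    a, b = a[valid], b[valid]
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)

    def entropy(q):
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    hxy = entropy(p.ravel())
    if hxy == 0:  # both images constant: degenerate but defined as maximal
        return 2.0
    return (entropy(px) + entropy(py)) / hxy


def resample_to_grid(moving: Volume, target: Volume, transform: RigidTransform, order: int = 1) -> np.ndarray:
    """Sample ``moving`` on ``target``'s grid through a fixed->moving transform.

    Voxels that map outside the moving volume are NaN.
    """
    shape = target.shape
    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    pts = target.index_to_world(idx)
    src_idx = moving.world_to_index(transform.apply(pts))
    out = ndimage.map_coordinates(
        np.asarray(moving.data, dtype=float),
        src_idx.T,
        order=order,
        mode="constant",
        cval=np.nan,
    )
    return out.reshape(shape)


def _downsample(v: Volume, factor: int) -> Volume:
    if factor == 1:
        return v
    sm = ndimage.gaussian_filter(np.asarray(v.data, dtype=float), sigma=0.5 * factor)
    data = sm[::factor, ::factor, ::factor]
    return Volume(data, v.spacing * factor, v.origin.copy(), v.direction.copy())


def register_rigid(
    fixed: Volume,
    moving: Volume,
    bins: int = DEFAULT_BINS,
    levels: int = 3,
    initial: RigidTransform | None = None,
) -> RigidTransform:
    """Find the rigid transform (fixed->moving world map) maximizing NMI.

    Coarse-to-fine over ``levels`` resolutions (downsampling factor 2 with
    Gaussian pre-smoothing), Powell refinement at each level.  The returned
    objective is guaranteed >= the identity's objective at full resolution.

    Raises
    ------
    ValueError
        if the volumes do not overlap at the initial transform.
    """
    center = fixed.index_to_world((np.asarray(fixed.shape, dtype=float) - 1) / 2.0)
    p0 = np.zeros(6)
    if initial is not None:
        p0 = np.concatenate([initial.rotation_deg, initial.translation])

    # Pre-smooth both channels (sigma = 1 voxel).  Trilinear interpolation
    # smooths noise by a pose-dependent amount, which on sharp images biases
    # the NMI optimum toward maximally-smoothing poses; once both images are
    # intrinsically smooth the differential is negligible and the optimum
    # sits at the true alignment.
    fixed = Volume(
        ndimage.gaussian_filter(np.asarray(fixed.data, dtype=float), 1.0),
        fixed.spacing, fixed.origin, fixed.direction,
    )
    moving = Volume(
        ndimage.gaussian_filter(np.asarray(moving.data, dtype=float), 1.0),
        moving.spacing, moving.origin, moving.direction,
    )

    def make_objective(fx: Volume, mv: Volume, stride: int = 1):
        # Sample points sit at half-voxel offsets so that BOTH channels are
        # trilinearly interpolated at every pose.  Interpolation smooths
        # noise; sampling the fixed image on its own grid would make exact
        # grid alignment artificially sharp and bias the optimum.
        idx = np.stack(
            np.meshgrid(*[np.arange(0, n - 1, stride) + 0.5 for n in fx.shape], indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        pts = fx.index_to_world(idx)
        fflat = ndimage.map_coordinates(np.asarray(fx.data, dtype=float), idx.T, order=1)
        mdata = np.asarray(mv.data, dtype=float)

        def objective(p):
            t = RigidTransform(p[:3], p[3:], center)
            src_idx = mv.world_to_index(t.apply(pts))
            samp = ndimage.map_coordinates(mdata, src_idx.T, order=1, mode="constant", cval=np.nan)
            valid = np.isfinite(samp)
            if valid.sum() < 0.01 * samp.size:
                return 0.0  # essentially no overlap
            return -nmi(fflat[valid], samp[valid], bins)

        return objective

    # strided sampling keeps the objective ~O(130k) points at any resolution
    fine_stride = max(2, int(np.ceil((fixed.data.size / 130_000) ** (1 / 3))))
    obj_full = make_objective(fixed, moving, stride=fine_stride)
    if obj_full(p0) == 0.0:
        raise ValueError("volumes do not overlap at the initial transform")

    p = p0
    for lvl in reversed(range(levels)):
        factor = 2**lvl
        if lvl == 0:
            # finest level: native resolution, strided sampling for speed;
            # multi-start (coarse result + initial guess) escapes the odd
            # local NMI optimum the coarse pyramid can deliver
            obj = make_objective(fixed, moving, stride=fine_stride)
            starts = [p] if np.allclose(p, p0) else [p, p0]
            best = None
            for s in starts:
                res = optimize.minimize(
                    obj, s, method="Powell",
                    options={"xtol": 0.01, "ftol": 1e-8, "maxiter": 6},
                )
                if best is None or res.fun < best.fun:
                    best = res
            p = best.x
        else:
            fx, mv = _downsample(fixed, factor), _downsample(moving, factor)
            stride = max(1, int(np.ceil((fx.data.size / 130_000) ** (1 / 3))))
            obj = make_objective(fx, mv, stride=stride)
            res = optimize.minimize(
                obj, p, method="Powell",
                options={"xtol": 0.01, "ftol": 1e-8, "maxiter": 20},
            )
            p = res.x
    # the optimum must not be worse than where we started
    if obj_full(p) > obj_full(p0):
        p = p0
    return RigidTransform(p[:3], p[3:], center)


def warp_labels(lm: LabelMap, t: RigidTransform, target: Volume) -> LabelMap:
    """Transport a label map onto ``target``'s grid (nearest neighbour).

    ``t`` maps target-frame world points into the label map's frame.  No new
    label codes are introduced; out-of-domain voxels become background.
    """
    samp = resample_to_grid(
        Volume(lm.data.astype(float), lm.spacing, lm.origin, lm.direction), target, t, order=0
    )
    samp = np.where(np.isfinite(samp), samp, 0)
    return LabelMap(
        np.round(samp).astype(np.int16),
        target.spacing.copy(),
        target.origin.copy(),
        target.direction.copy(),
    )
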