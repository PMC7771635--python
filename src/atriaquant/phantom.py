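"""Synthetic paired angiographic/enhancement phantoms with known ground truth.

The phantom emulates the two acquisitions the fibrosis pipeline consumes:

* an angiographic channel (bright-blood): the chamber lumen is bright against
  a dark background, delineating the endocardium;
* an enhancement channel (late-enhancement-like): the blood pool sits at an
  intermediate level, the healthy thin wall is darker, and a contiguous
  "fibrotic" wall patch of known fractional coverage is painted bright.

Geometry is a thin-walled ellipsoidal atrial body with four tubular pulmonary
veins at fixed superior/inferior posterior positions (small seeded angular
jitter), an optional appendage modelled as an oblate lobe on a short neck,
and a mitral orifice where the wall is open and the adjacent blood pool is
labeled as valve.  The enhancement channel is generated on a grid that is
rigidly displaced from the angiographic grid by a known offset, so the
registration stage has a known answer.

Everything is evaluated analytically at voxel centres; identical specs
(including the seed) give bit-identical volumes.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .io import LABEL_BLOOD_POOL, LABEL_MV, LABEL_VEINS, LabelMap, Volume

# Unit directions of the four vein axes (left/right x superior/inferior), all
# on the posterior aspect, plus the appendage axis (anterior-left).
_VEIN_DIRECTIONS = np.array(
    [
        [0.70, 0.55, 0.55],   # right superior
        [-0.70, 0.55, 0.55],  # left superior
        [0.70, 0.55, -0.55],  # right inferior
        [-0.70, 0.55, -0.55], # left inferior
    ]
)
_VEIN_DIRECTIONS /= np.linalg.norm(_VEIN_DIRECTIONS, axis=1, keepdims=True)
_APPENDAGE_DIR = np.array([-0.60, -0.70, 0.35]) / np.linalg.norm([-0.60, -0.70, 0.35])
_APPENDAGE_NECK_RADIUS = 5.5   # mm
_APPENDAGE_NECK_LENGTH = 8.0   # mm
_APPENDAGE_LOBE_SEMIAXES = np.array([9.0, 8.0, 6.5])  # mm, oblate
_CAP_DIRECTION = np.array([0.0, 1.0, 0.0])  # posterior wall, fibrosis cap centre


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of one synthetic phantom pair.

    Intensity units are arbitrary; geometry is in mm.  ``rigid_offset`` is
    (tx, ty, tz) mm followed by (rx, ry, rz) degrees applied to the
    enhancement grid about the phantom centre.
    """

    body_semiaxes: tuple = (30.0, 25.0, 20.0)
    wall_thickness: float = 3.0
    n_veins: int = 4
    vein_radius: float = 5.0
    vein_length: float = 25.0
    appendage: bool = True
    mv_orifice_radius: float = 12.0
    blood_mean: float = 100.0
    blood_sd: float = 10.0
    wall_mean: float = 60.0
    enhancement_mean: float = 200.0
    noise_sd: float = 5.0
    fibrosis_fraction: float = 0.3
    rigid_offset: tuple = (2.0, -3.0, 1.5, 2.0, -1.0, 1.5)
    grid_shape: tuple = (160, 160, 160)
    spacing: tuple = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.fibrosis_fraction <= 1.0:
            raise ValueError("fibrosis_fraction must lie in [0, 1]")
        if self.wall_thickness <= 0:
            raise ValueError("wall_thickness must be positive")
        if np.any(np.asarray(self.spacing) <= 0):
            raise ValueError("spacing components must be positive")
        if self.enhancement_mean <= self.wall_mean:
            raise ValueError("enhancement_mean must exceed wall_mean")
        if not 0 <= self.n_veins <= len(_VEIN_DIRECTIONS):
            raise ValueError(f"n_veins must be in [0, {len(_VEIN_DIRECTIONS)}]")

    # -- plain-text (key=value) serialization ------------------------------
    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (tuple, list, np.ndarray)):
                v = ",".join(repr(float(x)) for x in v)
            lines.append(f"{f.name}={v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PhantomSpec":
        kwargs = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key = key.strip()
            raw = raw.strip()
            if key not in fields:
                raise ValueError(f"unknown phantom parameter '{key}'")
            default = fields[key].default
            if isinstance(default, tuple):
                val = tuple(float(x) for x in raw.split(","))
                if key == "grid_shape":
                    val = tuple(int(x) for x in val)
            elif isinstance(default, bool):
                val = raw.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                val = int(raw)
            else:
                val = float(raw)
            kwargs[key] = val
        return cls(**kwargs)

    def save(self, path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path) -> "PhantomSpec":
        return cls.from_text(Path(path).read_text())


@dataclasses.dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom pair (defined on the angiographic grid)."""

    labels: LabelMap
    fibrosis_mask: np.ndarray     # boolean over the grid, True on fibrotic wall voxels
    true_burden: float            # fibrotic wall voxels / total body wall voxels
    body_volume: float            # mm^3, analytic ellipsoid volume
    body_surface_area: float      # mm^2, Knud Thomsen approximation


# ---------------------------------------------------------------------------
# analytic geometry helpers (vectorised over (...,3) point arrays)
# ---------------------------------------------------------------------------

def _ellipsoid_level(pts, center, semiaxes):
    d = (pts - center) / np.asarray(semiaxes, dtype=pts.dtype)
    return np.sqrt(np.einsum("...i,...i->...", d, d))


def _segment_distance(pts, p0, p1):
    """Euclidean distance from points to the segment p0-p1."""
    axis = (p1 - p0).astype(pts.dtype)
    L2 = float(axis @ axis)
    t = np.clip(((pts - p0.astype(pts.dtype)) @ axis) / L2, 0.0, 1.0)
    d = pts - p0.astype(pts.dtype) - t[..., np.newaxis] * axis
    return np.sqrt(np.einsum("...i,...i->...", d, d))


def _rotation_matrix(angles_deg):
    rx, ry, rz = np.deg2rad(angles_deg)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _jittered_axes(spec: PhantomSpec, rng: np.random.Generator):
    """Vein/appendage directions with small seeded angular jitter (<= ~3 deg)."""
    dirs = []
    for d in _VEIN_DIRECTIONS[: spec.n_veins]:
        jitter = _rotation_matrix(rng.uniform(-3.0, 3.0, size=3))
        dirs.append(jitter @ d)
    app = None
    if spec.appendage:
        app = _rotation_matrix(rng.uniform(-3.0, 3.0, size=3)) @ _APPENDAGE_DIR
    return dirs, app


class _PhantomGeometry:
    """Analytic predicates for the phantom tissue classes, in world mm."""

    def __init__(self, spec: PhantomSpec, center: np.ndarray, rng: np.random.Generator):
        self.spec = spec
        self.center = center
        a = np.asarray(spec.body_semiaxes, dtype=float)
        self.semiaxes = a
        self.outer_semiaxes = a + spec.wall_thickness
        self.vein_dirs, self.app_dir = _jittered_axes(spec, rng)
        # vein axes run from just inside the body surface outward
        self.vein_segments = []
        for d in self.vein_dirs:
            surface_pt = center + d / np.linalg.norm(d / a)  # ray-ellipsoid intersection
            p0 = center + 0.75 * (surface_pt - center)        # ensure lumen connectivity
            p1 = surface_pt + spec.vein_length * d
            self.vein_segments.append((p0, p1))
        self.app_neck = self.app_lobe_center = None
        if self.app_dir is not None:
            d = self.app_dir
            surface_pt = center + d / np.linalg.norm(d / a)
            p0 = center + 0.75 * (surface_pt - center)
            p1 = surface_pt + _APPENDAGE_NECK_LENGTH * d
            self.app_neck = (p0, p1)
            self.app_lobe_center = p1 + 0.5 * _APPENDAGE_LOBE_SEMIAXES[0] * d
        self.mv_center = center + np.array([0.0, 0.0, -a[2]])
        self.mv_radius = spec.mv_orifice_radius

    def max_extent(self) -> float:
        """Largest distance from the centre reached by any tissue, in mm."""
        r = float(np.max(self.outer_semiaxes))
        for p0, p1 in self.vein_segments:
            r = max(r, np.linalg.norm(p1 - self.center) + self.spec.vein_radius + self.spec.wall_thickness)
        if self.app_lobe_center is not None:
            r = max(
                r,
                np.linalg.norm(self.app_lobe_center - self.center)
                + float(np.max(_APPENDAGE_LOBE_SEMIAXES))
                + self.spec.wall_thickness,
            )
        return r

    # tissue predicates --------------------------------------------------
    def body_interior(self, pts):
        return _ellipsoid_level(pts, self.center, self.semiaxes) <= 1.0

    def _vein_lumen(self, pts, pad=0.0):
        out = np.zeros(pts.shape[:-1], dtype=bool)
        for p0, p1 in self.vein_segments:
            out |= _segment_distance(pts, p0, p1) <= self.spec.vein_radius + pad
        return out

    def _app_lumen(self, pts, pad=0.0):
        out = np.zeros(pts.shape[:-1], dtype=bool)
        if self.app_neck is not None:
            out |= _segment_distance(pts, *self.app_neck) <= _APPENDAGE_NECK_RADIUS + pad
            out |= _ellipsoid_level(pts, self.app_lobe_center, _APPENDAGE_LOBE_SEMIAXES + pad) <= 1.0
        return out

    def mv_region(self, pts):
        d = pts - self.mv_center.astype(pts.dtype)
        return np.einsum("...i,...i->...", d, d) <= self.mv_radius**2

    def classify(self, pts):
        """Return (labels, body_wall, branch_wall) for world points.

        ``labels`` uses the 4-code convention; ``body_wall``/``branch_wall``
        are boolean wall masks (the mitral orifice region carries no wall).
        Each distance field is evaluated once and reused for the lumen and
        the padded (wall) predicate.
        """
        t = self.spec.wall_thickness
        interior = self.body_interior(pts)
        # nearest-branch distance, shared by lumen and wall predicates
        vein_lumen = np.zeros(pts.shape[:-1], dtype=bool)
        vein_outer = np.zeros(pts.shape[:-1], dtype=bool)
        for p0, p1 in self.vein_segments:
            d = _segment_distance(pts, p0, p1)
            vein_lumen |= d <= self.spec.vein_radius
            vein_outer |= d <= self.spec.vein_radius + t
        if self.app_neck is not None:
            d = _segment_distance(pts, *self.app_neck)
            vein_lumen |= d <= _APPENDAGE_NECK_RADIUS
            vein_outer |= d <= _APPENDAGE_NECK_RADIUS + t
            lv = _ellipsoid_level(pts, self.app_lobe_center, _APPENDAGE_LOBE_SEMIAXES)
            vein_lumen |= lv <= 1.0
            vein_outer |= _ellipsoid_level(pts, self.app_lobe_center, _APPENDAGE_LOBE_SEMIAXES + t) <= 1.0
        vein = vein_lumen & ~interior
        mv = self.mv_region(pts)
        outer = _ellipsoid_level(pts, self.center, self.outer_semiaxes) <= 1.0
        lumen = interior | vein
        body_wall = outer & ~lumen & ~mv
        branch_wall = vein_outer & ~lumen & ~body_wall & ~mv
        labels = np.zeros(pts.shape[:-1], dtype=np.int16)
        labels[interior] = LABEL_BLOOD_POOL
        labels[vein] = LABEL_VEINS
        labels[interior & mv] = LABEL_MV
        return labels, body_wall, branch_wall

    def cap_angle(self, pts):
        """Angle (rad) between the centre->point direction and the cap axis."""
        d = pts - self.center
        d = d / np.maximum(np.linalg.norm(d, axis=-1, keepdims=True), 1e-12)
        return np.arccos(np.clip(d @ _CAP_DIRECTION, -1.0, 1.0))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _grid_points(shape, spacing):
    # float32 keeps the working set small; geometry tolerances are >> 1e-3 mm
    idx = np.stack(
        np.meshgrid(*[np.arange(n, dtype=np.float32) for n in shape], indexing="ij"),
        axis=-1,
    )
    return idx * np.asarray(spacing, dtype=np.float32)


def _paint_lge(geom: _PhantomGeometry, pts, fib_angle, rng):
    labels, body_wall, branch_wall = geom.classify(pts)
    lumen = labels > 0
    img = np.zeros(pts.shape[:-1], dtype=float)
    img[lumen] = rng.normal(geom.spec.blood_mean, geom.spec.blood_sd, size=int(lumen.sum()))
    wall = body_wall | branch_wall
    img[wall] = geom.spec.wall_mean
    if fib_angle > 0:
        fib = body_wall & (geom.cap_angle(pts) <= fib_angle)
        img[fib] = geom.spec.enhancement_mean
    return img


def generate_phantom(spec: PhantomSpec):
    """Generate one paired phantom.

    Returns
    -------
    mra : Volume
        Angiographic channel (bright lumen), identity grid.
    lge : Volume
        Enhancement channel on a grid rigidly displaced by ``spec.rigid_offset``.
    truth : PhantomTruth
        Ground-truth labels, fibrosis mask and burden on the angiographic grid.

    Raises
    ------
    ValueError
        if the requested geometry does not fit inside the grid.
    """
    spec = dataclasses.replace(spec)  # defensive copy
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    extent = (np.asarray(shape) - 1) * spacing
    center = extent / 2.0

    rng = np.random.default_rng(spec.seed)
    geom = _PhantomGeometry(spec, center, rng)
    margin = float(np.max(spacing))
    if geom.max_extent() > float(np.min(extent / 2.0)) - margin:
        raise ValueError(
            f"phantom geometry (radius {geom.max_extent():.1f} mm) exceeds the "
            f"grid half-extent {float(np.min(extent / 2.0)):.1f} mm"
        )

    pts = _grid_points(shape, spacing)
    labels, body_wall, _ = geom.classify(pts)

    # fibrosis cap: grow a geodesic cap on the posterior body wall voxel by
    # voxel (in order of angular distance from the cap axis) until the target
    # fraction of wall voxels is covered
    n_wall = int(body_wall.sum())
    wall_angles = geom.cap_angle(pts[body_wall])
    if spec.fibrosis_fraction > 0 and n_wall > 0:
        k = min(max(int(round(spec.fibrosis_fraction * n_wall)), 0), n_wall)
    else:
        k = 0
    fibrosis_mask = np.zeros(shape, dtype=bool)
    fib_angle = -1.0
    if k > 0:
        # exactly k voxels: ties at the cutoff angle broken by flat index
        wall_flat = np.flatnonzero(body_wall.ravel())
        order = np.lexsort((wall_flat, wall_angles))
        chosen = wall_flat[order[:k]]
        fibrosis_mask.ravel()[chosen] = True
        fib_angle = float(wall_angles[order[k - 1]])
    true_burden = k / n_wall if n_wall else 0.0

    # angiographic channel: bright lumen, dark elsewhere
    mra_data = np.zeros(shape, dtype=float)
    lumen = labels > 0
    mra_data[lumen] = rng.normal(spec.blood_mean, spec.blood_sd, size=int(lumen.sum()))
    if spec.noise_sd > 0:
        mra_data = mra_data + rng.normal(0.0, spec.noise_sd, size=shape)
    mra_data = np.clip(mra_data, 0.0, None)

    # enhancement channel on the displaced grid: voxel at world x sees the
    # tissue at T^-1(x), where T = (rotate about centre, then translate)
    t_off = np.asarray(spec.rigid_offset[:3], dtype=float)
    R = _rotation_matrix(spec.rigid_offset[3:])
    lge_pts = (pts - center - t_off) @ R + center  # (R^T = R^-1) applied row-wise
    lge_data = _paint_lge(geom, lge_pts, fib_angle, rng)
    if spec.noise_sd > 0:
        lge_data = lge_data + rng.normal(0.0, spec.noise_sd, size=shape)
    lge_data = np.clip(lge_data, 0.0, None)

    vol_ref, area_ref = analytic_shape_reference(spec)
    mra = Volume(mra_data, spacing, np.zeros(3))
    lge = Volume(lge_data, spacing, np.zeros(3))
    truth = PhantomTruth(
        labels=LabelMap(labels, spacing.copy(), np.zeros(3)),
        fibrosis_mask=fibrosis_mask,
        true_burden=float(true_burden),
        body_volume=vol_ref,
        body_surface_area=area_ref,
    )
    return mra, lge, truth


def rigid_offset_world_transform(spec: PhantomSpec):
    """The fixed->moving world map implied by ``spec.rigid_offset``.

    Returns (R, t, center) such that a tissue point x in the angiographic
    frame appears at R(x - center) + center + t in the enhancement frame.
    """
    shape = np.asarray(spec.grid_shape, dtype=float)
    spacing = np.asarray(spec.spacing, dtype=float)
    center = (shape - 1) * spacing / 2.0
    return _rotation_matrix(spec.rigid_offset[3:]), np.asarray(spec.rigid_offset[:3], dtype=float), center


def analytic_shape_reference(spec: PhantomSpec):
    """Closed-form volume and surface area of the (pure ellipsoid) body.

    Volume is exact, 4/3*pi*a*b*c; area uses the Knud Thomsen approximation
    (relative error below ~1.1% for any ellipsoid).
    """
    a, b, c = (float(x) for x in spec.body_semiaxes)
    volume = 4.0 / 3.0 * np.pi * a * b * c
    p = 1.6075
    area = 4.0 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0) ** (1.0 / p)
    return volume, area
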