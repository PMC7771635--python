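"""Multilabel anatomy labeling from a blood-pool mask.

The labeling pipeline turns a bright-blood volume into the 4-class label map
used throughout the package:

1. region growing from a seed voxel delineates the blood pool;
2. a medial (Voronoi-like) centerline model of the pool — skeleton voxels
   carrying maximal-inscribed-sphere radii from the interior distance
   transform — identifies tubular appendices (pulmonary veins, appendage);
3. each branch is clipped at its ostium, located where the inscribed-sphere
   radius profile, walking from the body outward, first falls below a fixed
   fraction of the body's maximal inscribed radius;
4. the mitral valve is labeled as the intersection of the blood pool with a
   sphere fitted through three user-supplied points on the orifice border.

All clipping operations only move voxels between label codes; the total
foreground count is conserved.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .io import LABEL_BLOOD_POOL, LABEL_MV, LABEL_VEINS, LabelMap, Volume

_STRUCT_6 = ndimage.generate_binary_structure(3, 1)
_STRUCT_26 = ndimage.generate_binary_structure(3, 3)

#: default ostium rule — clip where the medial radius falls below this
#: fraction of the body's maximal inscribed radius
DEFAULT_OSTIUM_FRACTION = 0.5
#: branches shorter than this (mm) are treated as skeletonization spurs
DEFAULT_MIN_BRANCH_LENGTH = 6.0


@dataclasses.dataclass
class Seed:
    """A region-growing seed: a voxel index inside the pool plus a tolerance."""

    index: tuple
    tolerance: float

    def __post_init__(self):
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")


@dataclasses.dataclass
class MvSphere:
    """Sphere through three points on the mitral-orifice border.

    The sphere's great circle is the circumcircle of the three points: the
    center is their circumcenter (in their common plane) and the radius the
    circumradius.
    """

    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    center: np.ndarray
    radius: float


@dataclasses.dataclass
class Branch:
    """One tubular appendix of the blood pool, ordered body -> tip."""

    path_idx: np.ndarray      # (n, 3) voxel indices along the medial path
    path_mm: np.ndarray       # (n, 3) world coordinates
    radii: np.ndarray         # (n,) inscribed-sphere radii, mm
    ostium_pos: np.ndarray | None = None   # mm
    ostium_normal: np.ndarray | None = None  # unit tangent, pointing distal
    ostium_index: int | None = None
    flagged: bool = False     # radius profile never crossed the threshold


@dataclasses.dataclass
class CenterlineModel:
    """Medial model of the blood pool: body radius plus one Branch per appendix."""

    body_max_radius: float
    branches: list
    skeleton_idx: np.ndarray  # (m, 3) all skeleton voxel indices
    skeleton_radii: np.ndarray  # (m,) inscribed radii at those voxels
    body_center_mm: np.ndarray | None = None  # position of the maximal inscribed sphere


# ---------------------------------------------------------------------------
# region growing
# ---------------------------------------------------------------------------

def region_grow(v: Volume, seed: Seed) -> LabelMap:
    """Grow the blood pool from a seed voxel.

    Includes exactly the voxels 6-connected-reachable from the seed whose
    intensity lies within ``seed.tolerance`` of the seed intensity.

    Raises
    ------
    ValueError
        if the seed sits in background (the grown region would be empty or
        the seed itself is out of range).
    """
    idx = tuple(int(i) for i in seed.index)
    data = np.asarray(v.data)
    seed_val = float(data[idx])
    if seed_val <= float(np.median(data)):
        raise ValueError(
            "seed appears to lie in background (intensity at or below the "
            "volume median); the grown blood pool would be empty"
        )
    within = np.abs(data - seed_val) <= seed.tolerance
    comp, _ = ndimage.label(within, structure=_STRUCT_6)
    grown = comp == comp[idx]
    labels = np.zeros(data.shape, dtype=np.int16)
    labels[grown] = LABEL_BLOOD_POOL
    return LabelMap(labels, v.spacing.copy(), v.origin.copy(), v.direction.copy())


# ---------------------------------------------------------------------------
# medial centerline model
# ---------------------------------------------------------------------------

def _skeleton_graph(skel_idx: np.ndarray, spacing: np.ndarray):
    """26-neighbour adjacency over skeleton voxels -> (neighbors list, edge mm)."""
    key = {tuple(p): i for i, p in enumerate(map(tuple, skel_idx))}
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    nbrs = [[] for _ in range(len(skel_idx))]
    for i, p in enumerate(skel_idx):
        for off in offsets:
            q = (p[0] + off[0], p[1] + off[1], p[2] + off[2])
            j = key.get(q)
            if j is not None:
                w = float(np.linalg.norm(np.asarray(off) * spacing))
                nbrs[i].append((j, w))
    return nbrs


def build_centerline(
    bp: LabelMap,
    ostium_fraction: float = DEFAULT_OSTIUM_FRACTION,
    min_branch_length: float = DEFAULT_MIN_BRANCH_LENGTH,
) -> CenterlineModel:
    """Build the medial centerline model of the blood pool.

    The interior distance transform supplies maximal-inscribed-sphere radii;
    the skeleton of the mask supplies the medial vertices.  Skeleton voxels
    with radius >= ``ostium_fraction`` x (body max radius) form the chamber
    core; connected skeleton components outside the core that touch it and
    extend at least ``min_branch_length`` mm are the branches.  A mask with
    no tubular appendices yields a body-only model (zero branches).

    Raises
    ------
    ValueError
        if the foreground is empty or not a single connected component.
    """
    mask = bp.data > 0
    if not mask.any():
        raise ValueError("empty blood-pool mask")
    ncomp = ndimage.label(mask, structure=_STRUCT_26)[1]
    if ncomp != 1:
        raise ValueError(f"blood pool must be a single component, found {ncomp}")

    # the medial model describes the solid chamber: interior holes (single
    # intensity outliers excluded by region growing) would otherwise puncture
    # the distance transform and collapse the core/branch decomposition
    mask = ndimage.binary_fill_holes(mask)
    dt = ndimage.distance_transform_edt(mask, sampling=bp.spacing)
    body_r = float(dt.max())
    skel = skeletonize(mask)
    skel_idx = np.argwhere(skel)
    skel_r = dt[skel]

    core = skel_r >= ostium_fraction * body_r
    if not core.any():  # degenerate: treat the global maximum as the core
        core = skel_r == skel_r.max()

    nbrs = _skeleton_graph(skel_idx, bp.spacing)
    n = len(skel_idx)

    # the chamber core is the connected core component holding the global
    # radius maximum; a large appendage lobe can form its own core island
    # and must not serve as a branch root
    core_comp = np.full(n, -1)
    cc = 0
    for start in range(n):
        if not core[start] or core_comp[start] >= 0:
            continue
        stack = [start]
        core_comp[start] = cc
        while stack:
            u = stack.pop()
            for vtx, _ in nbrs[u]:
                if core[vtx] and core_comp[vtx] < 0:
                    core_comp[vtx] = cc
                    stack.append(vtx)
        cc += 1
    body_core = core_comp[int(np.argmax(np.where(core, skel_r, -np.inf)))]
    in_body_core = core_comp == body_core
    body_center_mm = bp.index_to_world(skel_idx[int(np.argmax(np.where(in_body_core, skel_r, -np.inf)))])

    comp_id = np.full(n, -1)
    branches = []
    # connected components of the non-core skeleton
    cid = 0
    for start in range(n):
        if core[start] or comp_id[start] >= 0:
            continue
        stack, members = [start], []
        comp_id[start] = cid
        while stack:
            u = stack.pop()
            members.append(u)
            for vtx, _ in nbrs[u]:
                if not core[vtx] and comp_id[vtx] < 0:
                    comp_id[vtx] = cid
                    stack.append(vtx)
        cid += 1
        # root: member adjacent to the CHAMBER core; skip detached components
        roots = [u for u in members if any(in_body_core[j] for j, _ in nbrs[u])]
        if not roots:
            continue
        # farthest member from the root by graph distance = branch tip
        dist, prev = _dijkstra(nbrs, roots, set(members))
        tip = max(members, key=lambda u: dist.get(u, -1.0))
        if dist.get(tip, 0.0) < min_branch_length:
            continue
        path = [tip]
        while prev.get(path[-1]) is not None:
            path.append(prev[path[-1]])
        path = path[::-1]  # body -> tip
        p_idx = skel_idx[path]
        branches.append(
            Branch(
                path_idx=p_idx,
                path_mm=bp.index_to_world(p_idx),
                radii=skel_r[path].astype(float),
            )
        )
    branches.sort(key=lambda b: -len(b.path_idx))
    return CenterlineModel(
        body_max_radius=body_r,
        branches=branches,
        skeleton_idx=skel_idx,
        skeleton_radii=skel_r.astype(float),
        body_center_mm=body_center_mm,
    )


def _dijkstra(nbrs, sources, allowed):
    import heapq

    dist, prev = {}, {}
    pq = []
    for s in sources:
        dist[s] = 0.0
        prev[s] = None
        heapq.heappush(pq, (0.0, s))
    while pq:
        d, u = heapq.heappop(pq)
        if d > dist.get(u, np.inf):
            continue
        for vtx, w in nbrs[u]:
            if vtx not in allowed:
                continue
            nd = d + w
            if nd < dist.get(vtx, np.inf):
                dist[vtx] = nd
                prev[vtx] = u
                heapq.heappush(pq, (nd, vtx))
    return dist, prev


# ---------------------------------------------------------------------------
# ostium localization and clipping
# ---------------------------------------------------------------------------

#: refinement tolerance (mm): the ostium is advanced to the first vertex whose
#: radius is within this margin of the minimum radius further distal
_PLATEAU_TOL_MM = 0.5


def locate_ostium(
    cl: CenterlineModel,
    branch: int,
    fraction: float = DEFAULT_OSTIUM_FRACTION,
    refine: bool = True,
):
    """Locate a branch's ostium and clip plane.

    Walking from the body outward along the branch's medial path, the coarse
    ostium is the first vertex whose inscribed-sphere radius falls below
    ``fraction`` x (body max radius).  Because the medial radius decays
    gradually through the funnel between chamber and tube, the coarse vertex
    can sit well inside the body; with ``refine=True`` (default) the ostium
    is advanced distally to the first vertex whose radius comes within
    0.5 mm of the smallest radius anywhere further along the branch — for a
    tubular vein that is the start of the tube's radius plateau, for a lobed
    appendage the neck — which coincides with the geometric junction.  The
    clip-plane normal is the local centerline tangent, oriented toward the
    branch tip.  If the profile never falls below the coarse threshold the
    ostium is placed at the branch root and the branch is flagged.

    Returns the updated Branch (also stored back on the model).
    """
    b = cl.branches[branch]
    thresh = fraction * cl.body_max_radius
    below = np.nonzero(b.radii < thresh)[0]
    if len(below) == 0:
        i = 0
        b.flagged = True
    else:
        i = int(below[0])
        b.flagged = False
        if refine and len(b.radii) >= 4:
            # trim the branch tip, where the distance transform falls off at
            # the open end and would poison the distal minimum
            trim = max(2, int(round(b.radii[-1])) + 1)
            stop = max(i + 1, len(b.radii) - trim)
            suffix_min = np.minimum.accumulate(b.radii[i:stop][::-1])[::-1]
            at_neck = np.nonzero(b.radii[i:stop] <= suffix_min + _PLATEAU_TOL_MM)[0]
            if len(at_neck):
                i += int(at_neck[0])
    lo, hi = max(i - 2, 0), min(i + 2, len(b.path_mm) - 1)
    tangent = b.path_mm[hi] - b.path_mm[lo]
    norm = np.linalg.norm(tangent)
    if norm == 0:
        tangent, norm = np.array([0.0, 0.0, 1.0]), 1.0
    tangent = tangent / norm
    # the clip normal must point distal (away from the chamber)
    if cl.body_center_mm is not None and tangent @ (b.path_mm[i] - cl.body_center_mm) < 0:
        tangent = -tangent
    b.ostium_pos = b.path_mm[i].astype(float)
    b.ostium_normal = tangent
    b.ostium_index = i
    return b


def clip_veins(bp: LabelMap, cl: CenterlineModel) -> LabelMap:
    """Relabel voxels distal to each branch's clip plane as veins+appendage.

    For every branch with a located ostium, the pool voxels on the distal
    side of the clip plane that are connected to the branch's distal medial
    path are moved from code 1 to code 2.  A clip that would disconnect the
    remaining body is refused and the branch flagged.  Re-running on the
    result is a no-op (idempotent).
    """
    out = bp.data.copy()
    for b in cl.branches:
        if b.ostium_pos is None:
            raise ValueError("ostium not located for all branches; call locate_ostium first")
        pool = out == LABEL_BLOOD_POOL
        pts = bp.index_to_world(np.argwhere(pool))
        distal_half = (pts - b.ostium_pos) @ b.ostium_normal > 0
        half_mask = np.zeros(out.shape, dtype=bool)
        half_mask[tuple(np.argwhere(pool)[distal_half].T)] = True
        comp, ncomp = ndimage.label(half_mask, structure=_STRUCT_26)
        if ncomp == 0:
            continue
        # components containing the branch's distal medial voxels
        distal_path = b.path_idx[b.ostium_index:]
        ids = set(comp[tuple(distal_path.T)]) - {0}
        if not ids:
            continue  # already clipped (or plane beyond the tip): no-op
        to_move = np.isin(comp, list(ids))
        candidate = out.copy()
        candidate[to_move] = LABEL_VEINS
        body = candidate == LABEL_BLOOD_POOL
        # a clip must neither disconnect nor dominate the remaining body
        if ndimage.label(body, structure=_STRUCT_26)[1] != 1 or to_move.sum() > body.sum():
            b.flagged = True
            continue
        out = candidate
    return bp.copy_with(out)


# ---------------------------------------------------------------------------
# mitral valve sphere
# ---------------------------------------------------------------------------

def fit_mv_sphere(p1, p2, p3) -> MvSphere:
    """Fit the sphere whose great circle passes through three orifice points.

    Raises
    ------
    ValueError
        for (near-)collinear points.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    a = p2 - p1
    b = p3 - p1
    cross = np.cross(a, b)
    denom = 2.0 * float(cross @ cross)
    scale = max(np.linalg.norm(a), np.linalg.norm(b), 1e-12)
    if np.sqrt(float(cross @ cross)) < 1e-9 * scale**2:
        raise ValueError("the three points are collinear; no unique sphere")
    # circumcenter of the triangle, in its plane
    center = p1 + np.cross(float(a @ a) * b - float(b @ b) * a, cross) / denom
    radius = float(np.linalg.norm(center - p1))
    return MvSphere(p1, p2, p3, center, radius)


def label_mv(bp: LabelMap, s: MvSphere) -> LabelMap:
    """Relabel blood-pool voxels inside the sphere as mitral valve (code 3).

    A voxel belongs to the valve when its world-centre distance to the sphere
    centre is <= radius.  An empty intersection leaves the labels unchanged
    and emits a warning.
    """
    pool = bp.data == LABEL_BLOOD_POOL
    idx = np.argwhere(pool)
    d = np.linalg.norm(bp.index_to_world(idx) - s.center, axis=1)
    inside = d <= s.radius
    out = bp.data.copy()
    if not inside.any():
        warnings.warn("mitral-valve sphere does not intersect the blood pool; labels unchanged")
        return bp.copy_with(out)
    out[tuple(idx[inside].T)] = LABEL_MV
    return bp.copy_with(out)


# ---------------------------------------------------------------------------
# convenience: full automatic labeling of a bright-blood volume
# ---------------------------------------------------------------------------

def auto_label(
    v: Volume,
    seed: Seed,
    mv_points=None,
    ostium_fraction: float = DEFAULT_OSTIUM_FRACTION,
    min_branch_length: float = DEFAULT_MIN_BRANCH_LENGTH,
) -> LabelMap:
    """Region-grow, clip all branches, and optionally label the valve."""
    bp = region_grow(v, seed)
    cl = build_centerline(bp, ostium_fraction, min_branch_length)
    for i in range(len(cl.branches)):
        locate_ostium(cl, i, ostium_fraction)
    lm = clip_veins(bp, cl)
    if mv_points is not None:
        lm = label_mv(lm, fit_mv_sphere(*mv_points))
    return lm
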