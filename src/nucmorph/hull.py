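"""Gift-wrapping (Jarvis march) and the distance-restricted 2D hull.

The restricted hull is the edge-segmentation primitive: a convex-hull walk
over the boundary of a binary slice in which a hull edge is only accepted
when its physical length does not exceed a threshold distance ``td``.
Concavities whose mouth is spanned by a short hull edge are bridged
(filled); where the spanning edge is longer than ``td`` the original object
boundary is kept. All hull geometry is done in exact integer arithmetic on
pixel centers; ``td`` is compared in physical units so anisotropic slice
orientations (XZ, YZ) are handled by their in-plane calibration.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import line as draw_line

_STRUCT_8 = np.ones((3, 3), dtype=bool)


def _hull_candidates(points: np.ndarray) -> np.ndarray:
    """Per-row extreme pixels; every hull vertex is among them."""
    pts = np.asarray(points, dtype=np.int64)
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    rows = pts[:, 0]
    first = np.searchsorted(rows, np.unique(rows), side="left")
    last = np.searchsorted(rows, np.unique(rows), side="right") - 1
    cand = np.concatenate([pts[first], pts[last]])
    return np.unique(cand, axis=0)


def jarvis_march(points: np.ndarray) -> np.ndarray:
    """Convex-hull vertices of integer points by gift wrapping.

    Returns the hull polygon as an ordered ``(m, 2)`` integer array
    (collinear non-vertex points are skipped; a collinear input degenerates
    to its two extreme points). Exact integer arithmetic throughout.
    """
    pts_arr = np.unique(np.asarray(points, dtype=np.int64), axis=0)
    if len(pts_arr) <= 2:
        return pts_arr
    pts_arr = _hull_candidates(pts_arr)
    pts = [tuple(int(v) for v in p) for p in pts_arr]
    n = len(pts)
    if n <= 2:
        return pts_arr
    start = min(range(n), key=lambda i: pts[i])
    hull = []
    cur = start
    while True:
        hull.append(cur)
        px, py = pts[cur]
        cand = None
        for t in range(n):
            if t == cur:
                continue
            if cand is None:
                cand = t
                continue
            ax, ay = pts[cand]
            bx, by = pts[t]
            cr = (ax - px) * (by - py) - (ay - py) * (bx - px)
            if cr < 0:
                cand = t
            elif cr == 0:
                da = (ax - px) ** 2 + (ay - py) ** 2
                db = (bx - px) ** 2 + (by - py) ** 2
                if db > da:
                    cand = t
        cur = cand
        if cur == start:
            break
        if len(hull) > n:  # cannot happen with exact arithmetic
            raise RuntimeError("gift wrapping failed to close the hull")
    return np.array([pts[i] for i in hull], dtype=np.int64)


def rasterize_convex_polygon(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Pixels whose centers lie inside or on a convex polygon.

    Uses half-plane tests with exact integer cross products; degenerate
    polygons (segment, point) rasterize to exactly the lattice points of
    the segment/point, which keeps the region equal to the true convex
    hull of the input point set.
    """
    verts = np.asarray(vertices, dtype=np.int64)
    out = np.zeros(shape, dtype=bool)
    if len(verts) == 0:
        return out
    r0, c0 = verts.min(axis=0)
    r1, c1 = verts.max(axis=0)
    r0c, r1c = max(r0, 0), min(r1, shape[0] - 1)
    c0c, c1c = max(c0, 0), min(c1, shape[1] - 1)
    if r0c > r1c or c0c > c1c:
        return out
    rr, cc = np.meshgrid(
        np.arange(r0c, r1c + 1, dtype=np.int64),
        np.arange(c0c, c1c + 1, dtype=np.int64),
        indexing="ij",
    )
    inside = np.ones(rr.shape, dtype=bool)
    m = len(verts)
    if m == 1:
        region = (rr == verts[0, 0]) & (cc == verts[0, 1])
    else:
        # orient counterclockwise by signed area; a degenerate (zero-area)
        # polygon leaves only the cross == 0 band inside its bbox
        area2 = 0
        for i in range(m):
            r_a, c_a = verts[i]
            r_b, c_b = verts[(i + 1) % m]
            area2 += int(r_a) * int(c_b) - int(r_b) * int(c_a)
        vs = verts if area2 >= 0 else verts[::-1]
        for i in range(m):
            r_a, c_a = vs[i]
            r_b, c_b = vs[(i + 1) % m]
            if r_a == r_b and c_a == c_b:
                continue
            cr = (r_b - r_a) * (cc - c_a) - (c_b - c_a) * (rr - r_a)
            inside &= cr >= 0 if area2 != 0 else cr == 0
        region = inside
    out[r0c:r1c + 1, c0c:c1c + 1] = region
    return out


def restricted_hull_2d(
    slice2d: np.ndarray,
    td: float,
    spacing: tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """Distance-restricted convex hull of a binary 2D slice.

    ``spacing`` is the physical pixel size along (row, col). The output is
    a superset of the input foreground and a subset of its filled convex
    hull; interior holes are always filled, and each hull pocket is filled
    only when every hull edge adjacent to it is no longer than ``td``.
    With ``td = inf`` the result is exactly the filled convex hull.
    """
    fg = np.asarray(slice2d, dtype=bool)
    if not fg.any():
        return fg.copy()
    if td <= 0 and not math.isinf(td):
        raise ValueError("td must be positive")
    filled = ndi.binary_fill_holes(fg)
    boundary = filled & ~ndi.binary_erosion(filled)
    pts = np.argwhere(boundary)
    verts = jarvis_march(pts)
    hull_region = rasterize_convex_polygon(verts, fg.shape)
    hull_region |= filled  # guard; filled centers always lie in the hull
    if math.isinf(td):
        return hull_region

    pockets = hull_region & ~filled
    if not pockets.any():
        return hull_region
    lab, n_lab = ndi.label(pockets, structure=_STRUCT_8)
    blocked: set[int] = set()
    s0, s1 = spacing
    m = len(verts)
    if m >= 2:
        for i in range(m):
            r_a, c_a = verts[i]
            r_b, c_b = verts[(i + 1) % m]
            if r_a == r_b and c_a == c_b:
                continue
            length = math.hypot((r_b - r_a) * s0, (c_b - c_a) * s1)
            if length <= td:
                continue
            edge = np.zeros(fg.shape, dtype=bool)
            rr, cc = draw_line(int(r_a), int(c_a), int(r_b), int(c_b))
            edge[rr, cc] = True
            edge = ndi.binary_dilation(edge, structure=_STRUCT_8)
            blocked.update(int(v) for v in np.unique(lab[edge]) if v != 0)
    if blocked:
        keep = ~np.isin(lab, sorted(blocked)) & pockets
    else:
        keep = pockets
    return filled | keep
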