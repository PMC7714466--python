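"""Gift-wrapping hull core: exactness, restriction by td, growth bounds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi

from nucmorph import jarvis_march, restricted_hull_2d


# ---------------------------------------------------------------------------
# independent convex-hull membership oracle (Caratheodory: a point of the
# plane lies in conv(S) iff it lies in a triangle or segment over S)

def convex_membership_oracle(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    pts = np.asarray(points, dtype=np.int64)
    out = np.zeros(shape, dtype=bool)
    r0, c0 = pts.min(axis=0)
    r1, c1 = pts.max(axis=0)
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    q = np.stack([rr.ravel(), cc.ravel()], axis=1)  # (m, 2) candidates

    def cross(a, b, p):
        return (b[:, 0] - a[:, 0])[:, None] * (p[None, :, 1] - a[:, None, 1]) - (
            b[:, 1] - a[:, 1]
        )[:, None] * (p[None, :, 0] - a[:, None, 0])

    inside = np.zeros(len(q), dtype=bool)
    n = len(pts)
    # segments (covers collinear/degenerate cases)
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    a, b = pts[ii.ravel()], pts[jj.ravel()]
    col = cross(a, b, q) == 0
    within = (
        (q[None, :, 0] >= np.minimum(a[:, 0], b[:, 0])[:, None])
        & (q[None, :, 0] <= np.maximum(a[:, 0], b[:, 0])[:, None])
        & (q[None, :, 1] >= np.minimum(a[:, 1], b[:, 1])[:, None])
        & (q[None, :, 1] <= np.maximum(a[:, 1], b[:, 1])[:, None])
    )
    inside |= (col & within).any(axis=0)
    # proper triangles
    idx = np.indices((n, n, n)).reshape(3, -1).T
    a, b, c = pts[idx[:, 0]], pts[idx[:, 1]], pts[idx[:, 2]]
    area = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
    keep = area != 0
    a, b, c = a[keep], b[keep], c[keep]
    if len(a):
        s1, s2, s3 = cross(a, b, q), cross(b, c, q), cross(c, a, q)
        tri = ((s1 >= 0) & (s2 >= 0) & (s3 >= 0)) | ((s1 <= 0) & (s2 <= 0) & (s3 <= 0))
        inside |= tri.any(axis=0)
    out[q[inside, 0], q[inside, 1]] = True
    return out


def brute_force_hull_vertices(points: np.ndarray) -> set:
    """O(n^3) all-pairs edge test: a point is a hull vertex iff it is not a
    convex combination of the others (not strictly inside any triangle or
    interior to any segment)."""
    pts = [tuple(p) for p in np.unique(np.asarray(points, dtype=np.int64), axis=0)]
    verts = set()
    for p in pts:
        others = [q for q in pts if q != p]
        redundant = False
        for i in range(len(others)):
            for j in range(i + 1, len(others)):
                a, b = others[i], others[j]
                cr = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
                if cr == 0:
                    if (
                        min(a[0], b[0]) <= p[0] <= max(a[0], b[0])
                        and min(a[1], b[1]) <= p[1] <= max(a[1], b[1])
                    ):
                        redundant = True
                for k in range(j + 1, len(others)):
                    c = others[k]
                    s1 = (a[0] - p[0]) * (b[1] - p[1]) - (a[1] - p[1]) * (b[0] - p[0])
                    s2 = (b[0] - p[0]) * (c[1] - p[1]) - (b[1] - p[1]) * (c[0] - p[0])
                    s3 = (c[0] - p[0]) * (a[1] - p[1]) - (c[1] - p[1]) * (a[0] - p[0])
                    if (s1 >= 0 and s2 >= 0 and s3 >= 0) or (s1 <= 0 and s2 <= 0 and s3 <= 0):
                        redundant = True
        if not redundant:
            verts.add(p)
    return verts


def disc(radius: int, pad: int = 3) -> np.ndarray:
    n = 2 * (radius + pad) + 1
    c = n // 2
    rr, cc = np.ogrid[:n, :n]
    return (rr - c) ** 2 + (cc - c) ** 2 <= radius**2


class TestJarvisMarch:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 14), st.integers(0, 14)),
                    min_size=1, max_size=12))
    def test_vertices_match_all_pairs_oracle(self, raw_points):
        pts = np.array(raw_points, dtype=np.int64)
        hull = jarvis_march(pts)
        expected = brute_force_hull_vertices(pts)
        assert set(map(tuple, hull)) == expected

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 14), st.integers(0, 14)),
                    min_size=1, max_size=12))
    def test_unrestricted_hull_equals_membership_oracle(self, raw_points):
        """td = inf reproduces exact convex-hull membership of the lattice."""
        pts = np.unique(np.array(raw_points, dtype=np.int64), axis=0)
        grid = np.zeros((16, 16), dtype=bool)
        grid[pts[:, 0], pts[:, 1]] = True
        result = restricted_hull_2d(grid, math.inf)
        assert np.array_equal(result, convex_membership_oracle(pts, grid.shape))


class TestRestrictedHull:
    def test_empty_slice_unchanged(self):
        empty = np.zeros((8, 8), dtype=bool)
        assert not restricted_hull_2d(empty, 5.0).any()

    def test_convex_disc_equals_full_hull(self):
        d = disc(9)
        full = restricted_hull_2d(d, math.inf)
        finite = restricted_hull_2d(d, 3.0)
        assert np.array_equal(finite, full)
        assert np.array_equal(full & d, d)  # growth-only

    def test_narrow_notch_filled_wide_notch_kept(self):
        td = 8.0
        base = disc(12)
        c = base.shape[0] // 2

        def notched(width):
            g = base.copy()
            half = width // 2
            g[: c + 1, c - half: c - half + width] = False
            return g

        narrow = notched(int(td / 2))  # mouth well under td
        wide = notched(int(3 * td))  # mouth 3x td

        filled = restricted_hull_2d(narrow, td)
        # every pocket mouth is below td: result equals the shape's full hull
        assert np.array_equal(filled, restricted_hull_2d(narrow, math.inf))
        # and the deep notch interior is bridged
        assert filled[c - 8: c, c - 1: c + 2].all()
        kept = restricted_hull_2d(wide, td)
        # the wide notch survives: its pixels stay background
        assert not kept[: c - 2, c - 2: c + 3].any()
        # while the rest still grows to the hull
        assert np.array_equal(kept & wide, wide)

    def test_anisotropic_spacing_scales_td(self):
        """A notch is judged by physical mouth width, not pixel count."""
        base = disc(12)
        c = base.shape[0] // 2
        g = base.copy()
        g[: c + 1, c - 3: c + 4] = False  # 7-pixel mouth
        fine = restricted_hull_2d(g, 8.0, spacing=(1.0, 1.0))  # 7 units <= td
        coarse = restricted_hull_2d(g, 8.0, spacing=(1.0, 2.0))  # 14 units > td
        assert fine[: c - 2, c - 1: c + 2].any()
        assert not coarse[: c - 2, c - 1: c + 2].any()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(1.0, 20.0))
    def test_growth_only_and_hull_bounded(self, seed, td):
        rng = np.random.default_rng(seed)
        g = np.zeros((24, 24), dtype=bool)
        n_blobs = rng.integers(1, 4)
        for _ in range(n_blobs):
            r, c = rng.integers(4, 20, size=2)
            rad = rng.integers(1, 5)
            rr, cc = np.ogrid[:24, :24]
            g |= (rr - r) ** 2 + (cc - c) ** 2 <= rad**2
        out = restricted_hull_2d(g, td)
        full = restricted_hull_2d(g, math.inf)
        assert np.array_equal(out & g, g)  # superset of the input
        assert not (out & ~full).any()  # subset of the full hull

    def test_interior_holes_always_filled(self):
        g = disc(8)
        c = g.shape[0] // 2
        g[c - 1: c + 2, c - 1: c + 2] = False
        out = restricted_hull_2d(g, 2.0)
        assert out[c, c]
        assert not ndi.binary_fill_holes(out).sum() > out.sum()
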