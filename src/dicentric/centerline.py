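"""Centerline extraction for single chromosomes.

A chromosome's centerline (central axis) is the 1-D path along which width
and intensity profiles are measured. Straight chromosomes nearly fill their
minimum-area bounding rectangle, so their centerline is simply the rectangle's
long symmetry axis. Bent chromosomes are thinned to a morphological skeleton
after a cleanup pass (opening, border smoothing, hole filling) that suppresses
the spurious side branches and holes thinning is prone to; the skeleton is
then pruned to a single two-endpoint path and extended at both ends along the
local slope, because thinning stops short of the chromosome tips.

Coordinates are (row, col), 0-based; points may be sub-pixel.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import MultiPoint
from skimage import morphology

from .segmentation import ChromosomeObject, ObjectKind

__all__ = [
    "Centerline",
    "RectInfo",
    "CenterlineConfig",
    "rect_fill_ratio",
    "straight_centerline",
    "preprocess_mask",
    "skeletonize_path",
    "extend_skeleton",
    "extract_centerline",
]


@dataclass(frozen=True)
class CenterlineConfig:
    straightness_threshold: float = 0.80  # fill ratio above which the rect axis is used
    prune_len: int = 5                    # skeleton side branches shorter than this are removed
    k_slope: int = 5                      # points in the end-slope fit
    max_extend: int = 20                  # cap on end extension, px


@dataclass
class Centerline:
    """Ordered centerline path with per-point unit normals."""

    points: np.ndarray   # (N, 2) float, (row, col)
    normals: np.ndarray  # (N, 2) float, unit length
    length_px: float
    low_confidence: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.normals = np.asarray(self.normals, dtype=float)
        if len(self.points) < 3:
            raise ValueError("centerline needs at least 3 points")
        if self.points.shape != self.normals.shape:
            raise ValueError("points and normals must align")

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class RectInfo:
    """Minimum-area rotated bounding rectangle of an object."""

    center: tuple[float, float]       # (row, col)
    size: tuple[float, float]         # (long, short)
    angle_rad: float                  # orientation of the long axis
    fill_ratio: float                 # object area / rect area, in (0, 1]


def _pixel_corner_cloud(mask: np.ndarray) -> np.ndarray:
    """Corners of the unit squares of the mask's boundary pixels, so the
    rotated rectangle encloses pixel areas, not just pixel centers."""
    boundary = mask & ~ndi.binary_erosion(mask)
    rr, cc = np.nonzero(boundary)
    pts = []
    for dr in (-0.5, 0.5):
        for dc in (-0.5, 0.5):
            pts.append(np.column_stack([rr + dr, cc + dc]))
    return np.concatenate(pts)


def rect_fill_ratio(obj: ChromosomeObject) -> RectInfo:
    """Minimum-area rotated rectangle and the object's fill ratio within it.

    A fill ratio near 1 means the chromosome is straight; low ratios mean
    severe bending.
    """
    if obj.area_px < 3:
        raise ValueError("object too small for a bounding rectangle")
    cloud = _pixel_corner_cloud(obj.mask)
    rect = MultiPoint(cloud).minimum_rotated_rectangle
    xy = np.asarray(rect.exterior.coords)[:4]  # (row, col) pairs
    e1 = xy[1] - xy[0]
    e2 = xy[2] - xy[1]
    l1, l2 = np.linalg.norm(e1), np.linalg.norm(e2)
    if l1 >= l2:
        long_len, short_len, long_vec = l1, l2, e1
    else:
        long_len, short_len, long_vec = l2, l1, e2
    rect_area = l1 * l2
    center = xy.mean(axis=0)
    angle = float(np.arctan2(long_vec[0], long_vec[1]))
    ratio = min(1.0, obj.area_px / rect_area)
    return RectInfo(
        center=(float(center[0]), float(center[1])),
        size=(float(long_len), float(short_len)),
        angle_rad=angle,
        fill_ratio=float(ratio),
    )


def _inside(mask: np.ndarray, pt: np.ndarray) -> bool:
    r, c = int(round(pt[0])), int(round(pt[1]))
    return 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and bool(mask[r, c])


def straight_centerline(obj: ChromosomeObject, rect: RectInfo) -> Centerline:
    """Centerline of a straight chromosome: the symmetry axis parallel to the
    long side of its minimum-area rectangle, sampled at unit steps and
    clipped to the mask."""
    d = np.array([np.sin(rect.angle_rad), np.cos(rect.angle_rad)])
    center = np.array(rect.center)
    half = rect.size[0] / 2.0
    ts = np.arange(-np.floor(half), np.floor(half) + 1.0)
    pts = center[None, :] + ts[:, None] * d[None, :]
    ok = np.array([_inside(obj.mask, p) for p in pts])
    # keep the contiguous in-mask run nearest the center
    if not ok.any():
        raise ValueError("rectangle midline misses the mask entirely")
    idx = np.nonzero(ok)[0]
    mid = len(ts) // 2
    runs = np.split(idx, np.nonzero(np.diff(idx) > 1)[0] + 1)
    run = min(runs, key=lambda r: abs(int(np.mean(r)) - mid))
    pts = pts[run]
    if len(pts) < 3:
        raise ValueError("straight centerline too short")
    normal = np.array([-d[1], d[0]])
    normals = np.tile(normal, (len(pts), 1))
    length = float(np.linalg.norm(pts[-1] - pts[0]))
    return Centerline(points=pts, normals=normals, length_px=length)


def preprocess_mask(obj: ChromosomeObject) -> ChromosomeObject:
    """Cleanup before thinning: morphological opening (3x3), border smoothing
    with a 3x3 median filter, and hole filling. Falls back to hole filling
    alone if the cleanup erases or distorts the object (area change > 20%)."""
    padded = np.pad(obj.mask, 2)
    cleaned = ndi.binary_opening(padded, structure=np.ones((3, 3)))
    cleaned = ndi.median_filter(cleaned.astype(np.uint8), size=3) > 0
    cleaned = cleaned[2:-2, 2:-2]
    # fill after cropping: cropping can land a hole's drain channel outside
    # the crop, leaving an enclosed pore that would make thinning cyclic
    cleaned = ndi.binary_fill_holes(cleaned)
    area = int(cleaned.sum())
    if area == 0 or abs(area - obj.area_px) > 0.2 * obj.area_px:
        cleaned = ndi.binary_fill_holes(obj.mask)
        area = int(cleaned.sum())
    return ChromosomeObject(
        object_id=obj.object_id,
        mask=cleaned,
        bbox=obj.bbox,
        gray_crop=obj.gray_crop,
        area_px=area,
        kind=obj.kind,
    )


def _neighbors(pix: set[tuple[int, int]], p: tuple[int, int]) -> list[tuple[int, int]]:
    r, c = p
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            q = (r + dr, c + dc)
            if q in pix:
                out.append(q)
    return out


def _endpoints_junctions(pix: set) -> tuple[list, list]:
    ends, junes = [], []
    for p in pix:
        deg = len(_neighbors(pix, p))
        if deg == 1:
            ends.append(p)
        elif deg >= 3:
            junes.append(p)
    return sorted(ends), sorted(junes)


def skeletonize_path(obj: ChromosomeObject, prune_len: int = 5) -> np.ndarray:
    """Thin the (preprocessed) mask to a 1-px skeleton, prune short side
    branches until exactly two endpoints remain, and return the path ordered
    endpoint to endpoint as an (N, 2) integer array."""
    skel = morphology.skeletonize(obj.mask)
    pix = set(map(tuple, np.argwhere(skel)))
    if len(pix) < 3:
        raise ValueError("object too small: skeleton under 3 pixels")
    # iteratively remove the shortest terminal branch while the skeleton
    # still has junctions (or more than 2 endpoints)
    for _ in range(10 * len(pix)):
        ends, junes = _endpoints_junctions(pix)
        if len(ends) == 2 and not junes:
            break
        if not ends:
            # thinning can leave a small cycle (8-connectivity artifact even
            # in hole-free masks); break it and keep pruning
            pix.discard(min(pix))
            continue
        branches = []
        for e in ends:
            path = [e]
            prev = None
            cur = e
            while True:
                nxt = [q for q in _neighbors(pix, cur) if q != prev]
                if len(nxt) != 1:
                    break  # junction or dead end
                prev, cur = cur, nxt[0]
                if len(_neighbors(pix, cur)) >= 3:
                    break
                path.append(cur)
            branches.append(path)
        # remove the shortest terminal branch; preferring short ones first
        # implements "prune side twigs under prune_len", and repeating until
        # two endpoints remain also resolves genuinely branched skeletons
        branches.sort(key=len)
        for p in branches[0]:
            pix.discard(p)
        if len(pix) < 3:
            raise ValueError("pruning consumed the skeleton")
    ends, junes = _endpoints_junctions(pix)
    if len(ends) != 2 or junes:
        raise ValueError("could not reduce skeleton to a simple path")
    # trace from the lexicographically smaller endpoint
    start = ends[0]
    path = [start]
    prev = None
    cur = start
    while True:
        nxt = [q for q in _neighbors(pix, cur) if q != prev]
        # prefer 4-connected steps so diagonals do not skip path pixels
        nxt = [q for q in nxt if q not in path]
        if not nxt:
            break
        nxt.sort(key=lambda q: abs(q[0] - cur[0]) + abs(q[1] - cur[1]))
        prev, cur = cur, nxt[0]
        path.append(cur)
    if len(path) != len(pix):
        # fall back: order by geodesic sweep (should not normally happen)
        raise ValueError("skeleton trace did not cover the path")
    return np.asarray(path, dtype=int)


def _end_direction(path: np.ndarray, k: int, at_start: bool) -> np.ndarray:
    """Outward unit direction at one end of the path, from a principal-axis
    fit of the last k points (a total-least-squares slope)."""
    seg = path[:k] if at_start else path[-k:]
    seg = seg.astype(float)
    ctr = seg.mean(axis=0)
    u, s, vt = np.linalg.svd(seg - ctr)
    d = vt[0]
    ref = (seg[0] - seg[-1]) if at_start else (seg[-1] - seg[0])
    if np.dot(d, ref) < 0:
        d = -d
    return d / np.linalg.norm(d)


def _tangents(points: np.ndarray) -> np.ndarray:
    """Smoothed tangents: central difference over a 5-point window, clamped
    at the ends."""
    n = len(points)
    t = np.zeros_like(points, dtype=float)
    for i in range(n):
        a = max(0, i - 2)
        b = min(n - 1, i + 2)
        t[i] = points[b] - points[a]
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return t / norms


def _recenter(points: np.ndarray, normals: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Slide each point along its normal to the midpoint of the mask chord.

    Thinning cuts the inner corner of bent chromosomes; an off-center
    centerline point inflates the distance-weighted width score (the sum of
    |t| over the chord grows with the square of the displacement), which
    fakes width bumps at bends. Recentring on the perpendicular chord
    removes the displacement.
    """
    out = points.copy()
    for i in range(len(points)):
        p, nrm = points[i], normals[i]
        reach = {}
        for sign in (-1.0, 1.0):
            t = 0.0
            while t < 50.0:
                q = p + sign * (t + 1.0) * nrm
                if not _inside(mask, q):
                    break
                t += 1.0
            reach[sign] = t
        shift = (reach[1.0] - reach[-1.0]) / 2.0
        out[i] = p + shift * nrm
    return out


def extend_skeleton(
    path: np.ndarray,
    obj: ChromosomeObject,
    k_slope: int = 5,
    max_extend: int = 20,
) -> Centerline:
    """Extend a pruned skeleton to the chromosome tips.

    Thinning stops short of the mask ends, so at each end the local slope is
    fitted over the last ``k_slope`` points and the path is extended along
    that ray in unit steps while it stays inside the mask (at most
    ``max_extend`` px). Normals are recomputed from smoothed tangents.
    """
    path = np.asarray(path, dtype=float)
    k = min(k_slope, len(path))
    segs = [path]
    hit_cap = False
    for at_start in (True, False):
        d = _end_direction(path, k, at_start)
        tip = path[0] if at_start else path[-1]
        ext = []
        for step in range(1, max_extend + 1):
            p = tip + step * d
            if not _inside(obj.mask, p):
                break
            ext.append(p)
        else:
            hit_cap = True
        if ext:
            ext = np.asarray(ext)
            if at_start:
                segs.insert(0, ext[::-1])
            else:
                segs.append(ext)
    pts = np.concatenate(segs)
    # two recentering passes: normals improve after the first correction
    for _ in range(2):
        tang = _tangents(pts)
        normals = np.column_stack([-tang[:, 1], tang[:, 0]])
        pts = _recenter(pts, normals, obj.mask)
    tang = _tangents(pts)
    normals = np.column_stack([-tang[:, 1], tang[:, 0]])
    length = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    return Centerline(points=pts, normals=normals, length_px=length,
                      low_confidence=hit_cap)


def extract_centerline(
    obj: ChromosomeObject, cfg: CenterlineConfig | None = None
) -> Centerline:
    """Full centerline extraction for one single chromosome.

    Straight chromosomes (rect fill ratio above the straightness threshold)
    take the rectangle-axis route; bent ones take preprocess -> thin ->
    prune -> extend.
    """
    cfg = cfg or CenterlineConfig()
    if obj.kind != ObjectKind.SINGLE:
        raise ValueError("centerlines are extracted for single chromosomes only")
    rect = rect_fill_ratio(obj)
    if rect.fill_ratio >= cfg.straightness_threshold:
        return straight_centerline(obj, rect)
    pre = preprocess_mask(obj)
    path = skeletonize_path(pre, prune_len=cfg.prune_len)
    return extend_skeleton(path, pre, k_slope=cfg.k_slope, max_extend=cfg.max_extend)
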