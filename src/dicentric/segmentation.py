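"""Chromosome segmentation by intensity clustering and seeded region growth.

A Giemsa-stained metaphase image is dark chromosomes on a light background.
Stage one clusters pixel intensities with k-means++ (k=2) to split foreground
from background, and extracts connected components as candidate objects.
Each object is classified as a single chromosome, a touching clump, or an
overlapping/cross clump by simple shape features. Touching clumps are split
by a second, clump-local k-means that keeps only the darker chromosome cores
("thinning" each chromosome to a seed), and the seeds are regrown to the
full clump mask with a simultaneous ring-by-ring watershed so the split
chromosomes keep their original outline.

Overlapping/cross clumps are not split automatically; they are routed to a
manual review queue.
"""
from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology
from sklearn.cluster import KMeans

__all__ = [
    "MetaphaseImage",
    "LabelMask",
    "ChromosomeObject",
    "KMeansParams",
    "ObjectKind",
    "ClassifierConfig",
    "ClumpSplitError",
    "kmeans_cluster_image",
    "extract_objects",
    "classify_object",
    "resegment_clump",
    "watershed_grow",
    "skeleton_stats",
]


class ObjectKind(str, enum.Enum):
    SINGLE = "single"
    TOUCHING_CLUMP = "touching_clump"
    OVERLAPPING_CLUMP = "overlapping_clump"


@dataclass
class MetaphaseImage:
    """An 8-bit grayscale metaphase micrograph."""

    pixels: np.ndarray
    image_id: str = ""
    true_dose_gy: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale array")
        if px.shape[0] < 32 or px.shape[1] < 32:
            raise ValueError("image dimensions must be >= 32")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")
        self.pixels = px.astype(np.uint8)


@dataclass
class LabelMask:
    """Integer label image; 0 is background. ``warning`` flags degenerate
    inputs (e.g. a uniform image that cannot be clustered)."""

    labels: np.ndarray
    warning: str | None = None


@dataclass
class ChromosomeObject:
    """One segmented chromosome or clump, cropped to its bounding box.

    ``bbox`` is (row0, col0, row1, col1), half-open, in full-image
    coordinates; ``mask`` and ``gray_crop`` share the bbox shape.
    """

    object_id: int
    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    gray_crop: np.ndarray
    area_px: int
    kind: ObjectKind = ObjectKind.SINGLE

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.area_px != int(self.mask.sum()):
            raise ValueError("area_px inconsistent with mask")
        r0, c0, r1, c1 = self.bbox
        if self.mask.shape != (r1 - r0, c1 - c0):
            raise ValueError("mask does not fit bbox")


@dataclass(frozen=True)
class KMeansParams:
    """k-means++ parameters: number of clusters, iteration cap, number of
    restarts (best run by within-cluster sum of squares), and seed."""

    cluster_count: int = 2
    termcrit_iters: int = 40
    attempts: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_count < 2:
            raise ValueError("cluster_count must be >= 2")
        if self.attempts < 1:
            raise ValueError("attempts must be >= 1")


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds for the single / touching / overlapping decision."""

    min_area_px: int = 20
    solidity_single: float = 0.85
    overlap_min_branches: int = 2
    overlap_min_endpoints: int = 4
    classify_spur_len: int = 9  # skeleton twigs shorter than this are not arms
    hole_min_px: int = 20  # enclosed holes smaller than this are pores, not crossings


class ClumpSplitError(RuntimeError):
    """A touching clump could not be split into >= 2 seeds; it should be
    reclassified as overlapping and sent to manual review."""


def _kmeans_1d(values: np.ndarray, weights: np.ndarray, params: KMeansParams) -> np.ndarray:
    """Weighted 1-D k-means++ over intensity levels; returns one center per
    cluster, sorted descending (so the darkest cluster has the highest
    cluster index)."""
    km = KMeans(
        n_clusters=params.cluster_count,
        init="k-means++",
        n_init=params.attempts,
        max_iter=params.termcrit_iters,
        tol=1.0,  # gray-level convergence epsilon
        random_state=params.rng_seed,
    )
    km.fit(values.reshape(-1, 1), sample_weight=weights)
    centers = np.sort(km.cluster_centers_.ravel())[::-1]
    return centers


def _assign_by_centers(gray: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Nearest-center assignment. Centers are sorted descending, so index 0
    (brightest) is background and the darkest cluster gets the top label."""
    d = np.abs(gray[..., None].astype(float) - centers[None, None, :])
    return np.argmin(d, axis=-1)


def kmeans_cluster_image(image: MetaphaseImage, params: KMeansParams | None = None) -> LabelMask:
    """Cluster pixel intensities with k-means++ to separate chromosomes from
    background.

    With the default k=2 the result is binary: label 1 is the lower-mean
    (dark, stained) cluster, label 0 the background. With k>2, clusters are
    relabeled by descending mean intensity so the darkest material always
    carries the highest label. A uniform image cannot be clustered and comes
    back all-background with a warning.
    """
    params = params or KMeansParams()
    gray = image.pixels
    counts = np.bincount(gray.ravel(), minlength=256)
    levels = np.nonzero(counts)[0]
    if len(levels) < params.cluster_count:
        warnings.warn("image has too few distinct gray levels to cluster")
        return LabelMask(np.zeros_like(gray, dtype=np.int32), warning="degenerate_image")
    centers = _kmeans_1d(levels.astype(float), counts[levels].astype(float), params)
    labels = _assign_by_centers(gray, centers).astype(np.int32)
    return LabelMask(labels)


def extract_objects(fg: LabelMask | np.ndarray, min_area_px: int = 20,
                    gray: np.ndarray | None = None) -> list[ChromosomeObject]:
    """Connected-component extraction of foreground objects.

    8-connected components smaller than ``min_area_px`` are discarded as
    stain impurities. Objects are sorted by descending area and numbered
    from 1. ``gray`` supplies the intensity crops (zeros if omitted).
    """
    labels = fg.labels if isinstance(fg, LabelMask) else np.asarray(fg)
    binary = labels > 0
    if gray is None:
        gray = np.zeros(binary.shape, dtype=np.uint8)
    cc = measure.label(binary, connectivity=2)
    objs: list[ChromosomeObject] = []
    for region in measure.regionprops(cc):
        if region.area < min_area_px:
            continue
        r0, c0, r1, c1 = region.bbox
        mask = cc[r0:r1, c0:c1] == region.label
        objs.append(
            ChromosomeObject(
                object_id=0,
                mask=mask,
                bbox=(r0, c0, r1, c1),
                gray_crop=np.asarray(gray)[r0:r1, c0:c1].copy(),
                area_px=int(region.area),
            )
        )
    objs.sort(key=lambda o: (-o.area_px, o.bbox))
    for i, o in enumerate(objs, start=1):
        o.object_id = i
    return objs


def _degree_map(pix: set[tuple[int, int]]) -> dict[tuple[int, int], int]:
    deg = {}
    for r, c in pix:
        d = 0
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr or dc) and (r + dr, c + dc) in pix:
                    d += 1
        deg[(r, c)] = d
    return deg


def skeleton_stats(mask: np.ndarray, spur_len: int = 5) -> tuple[int, int]:
    """(branch points, endpoints) of the morphological skeleton of ``mask``.

    Terminal twigs shorter than ``spur_len`` that hang off a junction are
    pruned first — thinning artifacts, not real chromosome arms — so a
    slightly ragged single chromosome still reads as an unbranched path.
    """
    skel = morphology.skeletonize(mask)
    pix = set(map(tuple, np.argwhere(skel)))
    if not pix:
        return 0, 0
    changed = True
    while changed:
        changed = False
        deg = _degree_map(pix)
        ends = [p for p, d in deg.items() if d == 1]
        for e in sorted(ends):
            if e not in pix:
                continue
            path = [e]
            prev, cur = None, e
            hit_junction = False
            while len(path) <= spur_len:
                nxt = [q for q in _nb8(pix, cur) if q != prev]
                if len(nxt) != 1:
                    break
                prev, cur = cur, nxt[0]
                if len(_nb8(pix, cur)) >= 3:
                    hit_junction = True
                    break
                path.append(cur)
            if hit_junction and len(path) < spur_len:
                for p in path:
                    pix.discard(p)
                changed = True
    deg = _degree_map(pix)
    branches = sum(1 for d in deg.values() if d >= 3)
    endpoints = sum(1 for d in deg.values() if d == 1)
    return branches, endpoints


def _nb8(pix: set, p: tuple[int, int]) -> list[tuple[int, int]]:
    r, c = p
    return [
        (r + dr, c + dc)
        for dr in (-1, 0, 1)
        for dc in (-1, 0, 1)
        if (dr or dc) and (r + dr, c + dc) in pix
    ]


def classify_object(obj: ChromosomeObject, cfg: ClassifierConfig | None = None) -> ObjectKind:
    """Classify an object as single / touching_clump / overlapping_clump.

    Features: skeleton branch-point and endpoint counts, whether the mask
    encloses a hole (a hallmark of two chromosomes crossing), and solidity
    (area over convex-hull area). An unbranched path with no hole is a
    single chromosome whatever its solidity — bent chromosomes are
    low-solidity singles; a compact high-solidity unbranched blob is also a
    single. A holed or many-armed object is an overlapping clump left for
    manual review; anything else is a touching clump to re-segment.
    The decision is stored on ``obj.kind`` and returned.
    """
    cfg = cfg or ClassifierConfig()
    region = measure.regionprops(obj.mask.astype(np.uint8))[0]
    solidity = region.solidity
    branches, endpoints = skeleton_stats(obj.mask, spur_len=cfg.classify_spur_len)
    hole_px = int(np.count_nonzero(ndi.binary_fill_holes(obj.mask) & ~obj.mask))
    has_hole = hole_px >= cfg.hole_min_px
    if has_hole or (
        branches >= cfg.overlap_min_branches and endpoints >= cfg.overlap_min_endpoints
    ):
        kind = ObjectKind.OVERLAPPING_CLUMP
    elif branches == 0 and (endpoints <= 2 or solidity >= cfg.solidity_single):
        kind = ObjectKind.SINGLE
    else:
        kind = ObjectKind.TOUCHING_CLUMP
    obj.kind = kind
    return kind


def resegment_clump(
    clump: ChromosomeObject,
    params: KMeansParams | None = None,
    min_seed_area: int = 10,
) -> list[np.ndarray]:
    """Split a touching clump into per-chromosome seed masks.

    k-means (k=2) is run on the gray values of the clump pixels only.
    Chromosome centers are stained darker than their edges, so keeping the
    darker cluster "thins" every chromosome and breaks the light contact
    zones between them. The 8-connected components of the retained core
    (each at least ``min_seed_area`` px) are the seeds.

    A chromosome's own core can break where the stain lightens at a
    centromeric constriction. Such breaks lie *along* the band, so core
    components separated by a short gap whose direction aligns with both
    components' local axes are re-merged into one seed; genuine contact
    between two chromosomes is side-on (the gap runs across at least one
    band's axis) and is never merged.

    Raises :class:`ClumpSplitError` when fewer than two seeds emerge — the
    clump cannot be split this way and belongs in the review queue.
    """
    params = params or KMeansParams()
    vals = clump.gray_crop[clump.mask].astype(float)
    levels, counts = np.unique(vals, return_counts=True)
    last_error = ClumpSplitError("clump gray levels are uniform; cannot split")
    # k=2 first; if the cores stay connected, adjust the clustering (k=3,
    # keeping only the darkest cluster) for a thinner core
    for k_try in (params.cluster_count, params.cluster_count + 1):
        if len(levels) < k_try:
            continue
        centers = _kmeans_1d(
            levels, counts.astype(float),
            KMeansParams(k_try, params.termcrit_iters, params.attempts, params.rng_seed),
        )
        # darkest cluster = lowest-mean center (highest index after sort)
        assign = np.argmin(np.abs(vals[:, None] - centers[None, :]), axis=1)
        core = np.zeros(clump.mask.shape, dtype=bool)
        core[clump.mask] = assign == (len(centers) - 1)
        cc = measure.label(core, connectivity=2)
        comps = [cc == lab for lab in range(1, cc.max() + 1)]
        comps = [c for c in comps if c.sum() >= 4]
        groups = _merge_collinear(comps)
        seeds = []
        for grp in groups:
            seed = np.zeros(clump.mask.shape, dtype=bool)
            for k in grp:
                seed |= comps[k]
            if seed.sum() >= min_seed_area:
                seeds.append(seed)
        if len(seeds) >= 2:
            # stable order: by top-left-most pixel, deterministic seed ids
            seeds.sort(key=lambda s: tuple(np.argwhere(s)[0]))
            return seeds
        last_error = ClumpSplitError(
            f"found {len(seeds)} seed(s); cannot split clump"
        )
    raise last_error


def _merge_collinear(
    comps: list[np.ndarray], max_gap: float = 9.0, min_cos: float = 0.7
) -> list[list[int]]:
    """Union-find grouping of core components that continue one another.

    Two components merge when their closest pixels are within ``max_gap``
    and the connecting direction aligns (|cos| >= ``min_cos``) with each
    component's local axis near the gap.
    """
    from scipy.spatial import cKDTree

    coords = [np.argwhere(c).astype(float) for c in comps]
    trees = [cKDTree(xy) for xy in coords]
    parent = list(range(len(comps)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(len(comps)):
        for j in range(i + 1, len(comps)):
            d, idx = trees[j].query(coords[i], workers=1)
            k = int(np.argmin(d))
            gap = float(d[k])
            if gap > max_gap:
                continue
            pi, pj = coords[i][k], coords[j][idx[k]]
            u = pj - pi
            nu = np.linalg.norm(u)
            if nu < 1e-9:
                aligned = True
            else:
                u = u / nu
                cosines = []
                for xy, p in ((coords[i], pi), (coords[j], pj)):
                    # radius ~ band width so tip blobs do not dominate the fit
                    near = xy[np.linalg.norm(xy - p, axis=1) <= 8.0]
                    if len(near) < 3:
                        cosines.append(1.0)
                        continue
                    _, _, vt = np.linalg.svd(near - near.mean(axis=0))
                    cosines.append(abs(float(np.dot(vt[0], u))))
                worst = min(cosines)
                # bent bands under-state alignment through the chord; allow a
                # borderline pair when bridging the gap yields an unbranched
                # path (side contacts form a branched T union instead)
                aligned = worst >= min_cos or (
                    worst >= 0.5 and _bridges_to_path(comps[i], comps[j])
                )
            if aligned:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list[int]] = {}
    for i in range(len(comps)):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def _bridges_to_path(a: np.ndarray, b: np.ndarray) -> bool:
    """True when dilating the union of two core components bridges them into
    a single unbranched band (skeleton with <= 2 endpoints, no junctions)."""
    union = a | b
    rows, cols = np.nonzero(union)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    crop = np.pad(union[r0:r1, c0:c1], 3)
    bridged = ndi.binary_dilation(crop, structure=np.ones((3, 3)), iterations=2)
    if measure.label(bridged, connectivity=2).max() != 1:
        return False
    branches, endpoints = skeleton_stats(bridged, spur_len=5)
    return branches == 0 and endpoints <= 2


_SHIFTS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _ring_grow(mask: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Simultaneous ring-by-ring geodesic growth of positive labels inside
    ``mask`` (8-connected). A pixel first reached on a given ring takes the
    minimum label among its already-labeled neighbors."""
    labels = labels.copy()
    big = labels.max() + 1
    while True:
        unassigned = mask & (labels == 0)
        if not unassigned.any():
            break
        nmin = np.full(labels.shape, big, dtype=labels.dtype)
        for dr, dc in _SHIFTS:
            shifted = np.full_like(labels, 0)
            rs = slice(max(dr, 0), labels.shape[0] + min(dr, 0))
            rd = slice(max(-dr, 0), labels.shape[0] + min(-dr, 0))
            cs = slice(max(dc, 0), labels.shape[1] + min(dc, 0))
            cd = slice(max(-dc, 0), labels.shape[1] + min(-dc, 0))
            shifted[rd, cd] = labels[rs, cs]
            np.minimum(nmin, np.where(shifted > 0, shifted, big), out=nmin)
        newly = unassigned & (nmin < big)
        if not newly.any():
            raise ValueError("mask pixels unreachable from any seed")
        labels[newly] = nmin[newly]
    return labels


def watershed_grow(
    clump: ChromosomeObject, seeds: list[np.ndarray]
) -> list[ChromosomeObject]:
    """Regrow seed masks to fill the clump, one pixel ring at a time.

    All seeds expand simultaneously and geodesically (8-connected, confined
    to the clump mask) until their fronts meet; a pixel reached by two
    fronts on the same ring goes to the lower seed id. Every clump pixel
    ends up with exactly one seed label. Returns one single-chromosome
    object per seed, in full-image coordinates.
    """
    if not seeds:
        raise ValueError("empty seed list")
    labels = np.zeros(clump.mask.shape, dtype=np.int32)
    for i, seed in enumerate(seeds, start=1):
        if seed.shape != clump.mask.shape:
            raise ValueError("seed shape must match clump mask")
        if np.any(seed & ~clump.mask):
            raise ValueError("seed extends outside the clump mask")
        if np.any(seed & (labels > 0)):
            raise ValueError("seeds must be pairwise disjoint")
        labels[seed] = i
    labels = _ring_grow(clump.mask, labels)
    r0c, c0c = clump.bbox[0], clump.bbox[1]
    out: list[ChromosomeObject] = []
    for i in range(1, len(seeds) + 1):
        m = labels == i
        rows, cols = np.nonzero(m)
        r0, r1 = rows.min(), rows.max() + 1
        c0, c1 = cols.min(), cols.max() + 1
        out.append(
            ChromosomeObject(
                object_id=i,
                mask=m[r0:r1, c0:c1],
                bbox=(r0c + r0, c0c + c0, r0c + r1, c0c + c1),
                gray_crop=clump.gray_crop[r0:r1, c0:c1].copy(),
                area_px=int(m.sum()),
                kind=ObjectKind.SINGLE,
            )
        )
    return out
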