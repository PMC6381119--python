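"""Synthetic metaphase phantoms with exact ground truth.

No public corpus of scored Giemsa metaphases exists, so every stage of the
pipeline is exercised on rendered phantoms: dark, elongated, gently bent
bands (chromosomes) on a light noisy background. Each band follows a random
cubic Bezier spine; its half-width narrows and its stain lightens smoothly at
each centromere position; the stain is darkest along the spine and lightens
toward the band edge (which is what lets the clump-splitting k-means "thin"
chromosomes to their cores). Bands can be placed in deliberate side contact
(touching clumps) or crossing (overlapping clumps), and small dark specks
emulate stain impurities.

The generator returns, for every image, the exact spine polylines, masks,
centromere arc positions, per-chromosome class labels and the clump adjacency
list, so segmentation, centerline, centromere and dose stages can all be
scored against truth.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .segmentation import MetaphaseImage

__all__ = [
    "PhantomSpec",
    "ChromosomeTruth",
    "PhantomTruth",
    "make_chromosome",
    "make_metaphase",
    "make_single_chromosome_image",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one synthetic metaphase.

    Defaults model a human metaphase spread (46 chromosomes) digitized at a
    scale where chromosomes are 45-90 px long and 7-11 px wide, with
    Giemsa-like contrast: light background (220 +- 8), dark band cores
    (60 +- 6 rendering noise), band edges lightened by up to 60 gray levels,
    and centromeric constrictions that halve the width and lighten the stain
    by 40 gray levels.
    """

    image_size: tuple[int, int] = (640, 640)
    n_chromosomes: int = 46
    n_dicentrics: int = 2
    length_range: tuple[float, float] = (45.0, 90.0)
    width_range: tuple[float, float] = (7.0, 11.0)
    curvature_range: tuple[float, float] = (0.0, 0.5)
    constriction_depth: float = 0.5
    constriction_lightening: float = 40.0
    background_gray: tuple[float, float] = (220.0, 8.0)   # (mean, sigma)
    foreground_gray: tuple[float, float] = (60.0, 6.0)    # (core mean, sigma)
    edge_lightening: float = 60.0
    touching_fraction: float = 0.1
    overlap_fraction: float = 0.0
    impurity_count: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dicentrics > self.n_chromosomes:
            raise ValueError("n_dicentrics cannot exceed n_chromosomes")
        if not (0.0 < self.constriction_depth < 1.0):
            raise ValueError("constriction depth must be in (0, 1)")


@dataclass
class ChromosomeTruth:
    """Ground truth for one rendered chromosome."""

    spine: np.ndarray                 # (S, 2) float, (row, col), ordered
    mask: np.ndarray                  # bool, canvas- or patch-sized
    centromere_fracs: list[float]     # arc-length fractions in (0, 1)
    centromere_points: np.ndarray     # (k, 2) float, on the spine
    n_centromeres: int
    label: str                        # monocentric / dicentric / ...


@dataclass
class PhantomTruth:
    """Ground truth for one synthetic metaphase image."""

    chromosomes: list[ChromosomeTruth]
    n_dicentrics: int
    adjacency: list[tuple[int, int, str]]  # (i, j, "touching"|"overlapping")


def _bezier(p0, p1, p2, p3, n):
    t = np.linspace(0.0, 1.0, n)[:, None]
    return ((1 - t) ** 3 * p0 + 3 * (1 - t) ** 2 * t * p1
            + 3 * (1 - t) * t**2 * p2 + t**3 * p3)


def _spine(length: float, curvature: float, rng: np.random.Generator) -> np.ndarray:
    """A canonical spine: cubic Bezier of roughly the requested arc length,
    bending by ``curvature`` (0 straight, 1 strongly bent), resampled to
    unit-ish spacing. Starts near the origin heading along +col."""
    bend = curvature * length * 0.45
    side = rng.choice([-1.0, 1.0])
    p0 = np.array([0.0, 0.0])
    p1 = np.array([side * bend, length / 3.0])
    p2 = np.array([side * bend, 2.0 * length / 3.0])
    p3 = np.array([0.0, length])
    pts = _bezier(p0, p1, p2, p3, max(8, int(4 * length)))
    # rescale so arc length matches `length`
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = seg.sum()
    pts *= length / arc
    return pts


def _transform(spine: np.ndarray, angle: float, offset: np.ndarray) -> np.ndarray:
    rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    return spine @ rot.T + offset[None, :]


def _arc_fracs(spine: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(spine, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    return arc / arc[-1]


def _bump(fracs: np.ndarray, centers: list[float], sigma: float) -> np.ndarray:
    b = np.zeros_like(fracs)
    for c in centers:
        b = np.maximum(b, np.exp(-0.5 * ((fracs - c) / sigma) ** 2))
    return b


def _render_band(
    spine: np.ndarray,
    width: float,
    centromeres: list[float],
    depth: float,
    lightening: float,
    core_gray: float,
    fg_sigma: float,
    edge_lightening: float,
    canvas_shape: tuple[int, int],
    rng: np.random.Generator,
    bump_sigma: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize one band onto a canvas-sized boolean mask + gray image.

    Width profile: w(s) = width * (1 - depth * bump(s)); stain profile:
    core + edge_lightening * (d / halfwidth)^2 + lightening * bump(s) + noise.
    Returns (mask, gray) where gray is only valid under the mask.
    """
    fracs = _arc_fracs(spine)
    bump = _bump(fracs, centromeres, bump_sigma)
    halfw = 0.5 * width * (1.0 - depth * bump)
    tree = cKDTree(spine)
    r0 = max(0, int(np.floor(spine[:, 0].min() - width)))
    r1 = min(canvas_shape[0], int(np.ceil(spine[:, 0].max() + width)) + 1)
    c0 = max(0, int(np.floor(spine[:, 1].min() - width)))
    c1 = min(canvas_shape[1], int(np.ceil(spine[:, 1].max() + width)) + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    pix = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    d, idx = tree.query(pix, workers=1)
    inside = d <= halfw[idx]
    mask = np.zeros(canvas_shape, dtype=bool)
    gray = np.zeros(canvas_shape, dtype=float)
    rows = pix[inside, 0].astype(int)
    cols = pix[inside, 1].astype(int)
    rel = np.clip(d[inside] / np.maximum(halfw[idx][inside], 0.5), 0.0, 1.0)
    g = (
        core_gray
        + edge_lightening * rel**2
        + lightening * bump[idx][inside]
        + rng.normal(0.0, fg_sigma, size=rel.shape)
    )
    mask[rows, cols] = True
    gray[rows, cols] = np.clip(g, 0.0, 255.0)
    return mask, gray


def make_chromosome(
    length: float,
    width: float,
    curvature: float,
    centromeres: list[float],
    depth: float = 0.5,
    seed: int = 0,
    lightening: float = 40.0,
    core_gray: float = 60.0,
    fg_sigma: float = 6.0,
    edge_lightening: float = 60.0,
) -> tuple[np.ndarray, np.ndarray, ChromosomeTruth]:
    """Render a single chromosome band in a tight local patch.

    ``centromeres`` are arc-length fractions, each in (0.15, 0.85) and
    pairwise separated by at least 0.2. Returns (mask, gray patch, truth);
    the gray patch is valid only under the mask.
    """
    if width > length / 3.0:
        raise ValueError("impossible geometry: width > length/3")
    for f in centromeres:
        if not (0.15 < f < 0.85):
            raise ValueError("centromere arc fractions must lie in (0.15, 0.85)")
    cs = sorted(centromeres)
    if any(b - a < 0.2 for a, b in zip(cs, cs[1:])):
        raise ValueError("centromere arc fractions must be >= 0.2 apart")
    rng = np.random.default_rng(seed)
    spine = _spine(length, curvature, rng)
    margin = width + 2.0
    spine = spine - spine.min(axis=0) + margin
    shape = (
        int(np.ceil(spine[:, 0].max() + margin)),
        int(np.ceil(spine[:, 1].max() + margin)),
    )
    mask, gray = _render_band(
        spine, width, centromeres, depth, lightening,
        core_gray, fg_sigma, edge_lightening, shape, rng,
    )
    truth = _truth_for(spine, mask, centromeres)
    return mask, gray, truth


def _truth_for(spine: np.ndarray, mask: np.ndarray, centromeres: list[float]) -> ChromosomeTruth:
    fracs = _arc_fracs(spine)
    pts = np.array([spine[np.argmin(np.abs(fracs - c))] for c in centromeres]) \
        if centromeres else np.zeros((0, 2))
    labels = {0: "acentric_like", 1: "monocentric", 2: "dicentric"}
    return ChromosomeTruth(
        spine=spine,
        mask=mask,
        centromere_fracs=list(centromeres),
        centromere_points=pts,
        n_centromeres=len(centromeres),
        label=labels.get(len(centromeres), "multicentric"),
    )


def _sample_centromeres(n: int, rng: np.random.Generator) -> list[float]:
    """n=1: one position in (0.2, 0.8); n=2: two positions >= 0.25 apart."""
    if n == 1:
        return [float(rng.uniform(0.2, 0.8))]
    for _ in range(100):
        a, b = np.sort(rng.uniform(0.2, 0.8, size=2))
        if b - a >= 0.25:
            return [float(a), float(b)]
    return [0.3, 0.7]


def _dilate(mask: np.ndarray, it: int = 1) -> np.ndarray:
    return ndi.binary_dilation(mask, structure=np.ones((3, 3)), iterations=it)


def _nearest_frac(spine: np.ndarray, point: np.ndarray) -> float:
    """Arc-length fraction of the spine point nearest to ``point``."""
    k = int(np.argmin(np.linalg.norm(spine - point[None, :], axis=1)))
    return float(_arc_fracs(spine)[k])


def _shift_mask(mask: np.ndarray, dr: int, dc: int) -> np.ndarray | None:
    """Translate a boolean mask by integer offsets; None if pixels would
    fall off the canvas."""
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        return mask
    r, c = rows + dr, cols + dc
    if r.min() < 0 or c.min() < 0 or r.max() >= mask.shape[0] or c.max() >= mask.shape[1]:
        return None
    out = np.zeros_like(mask)
    out[r, c] = True
    return out


def make_metaphase(spec: PhantomSpec) -> tuple[MetaphaseImage, PhantomTruth]:
    """Render a full synthetic metaphase with ground truth.

    The first ``n_dicentrics`` chromosomes carry two centromeres, the rest
    one. A ``touching_fraction`` of chromosomes is placed in side contact
    with a previously placed one (masks adjacent, not overlapping); an
    ``overlap_fraction`` is placed crossing one (masks overlapping). All
    other placements are kept clear of each other by a 2-px margin.
    Raises RuntimeError if placement fails after bounded retries.
    """
    rng = np.random.default_rng(spec.rng_seed)
    H, W = spec.image_size
    canvas = np.clip(
        rng.normal(spec.background_gray[0], spec.background_gray[1], size=(H, W)),
        0, 255,
    )
    occupied = np.zeros((H, W), dtype=bool)
    truths: list[ChromosomeTruth] = []
    masks: list[np.ndarray] = []
    adjacency: list[tuple[int, int, str]] = []

    n = spec.n_chromosomes
    n_touch = int(round(spec.touching_fraction * n))
    n_cross = int(round(spec.overlap_fraction * n))
    modes = ["free"] * n
    # contact placements need an anchor, so they never go first
    for k in range(n_touch):
        modes[n - 1 - k] = "touch"
    for k in range(n_cross):
        modes[1 + k] = "cross" if n > 1 else "free"

    def in_bounds(spine: np.ndarray, width: float) -> bool:
        return (
            spine[:, 0].min() >= width + 1 and spine[:, 0].max() <= H - width - 2
            and spine[:, 1].min() >= width + 1 and spine[:, 1].max() <= W - width - 2
        )

    for i in range(n):
        n_cen = 2 if i < spec.n_dicentrics else 1
        placed = False
        for attempt in range(300):
            length = rng.uniform(*spec.length_range)
            width = rng.uniform(*spec.width_range)
            curv = rng.uniform(*spec.curvature_range)
            cens = _sample_centromeres(n_cen, rng)
            spine0 = _spine(length, curv, rng)
            spine0 -= spine0.mean(axis=0)
            angle = rng.uniform(0.0, 2 * np.pi)
            mode = modes[i] if masks else "free"
            crng_seed = int(rng.integers(0, 2**31))
            if mode == "touch":
                # end-to-side contact: aim the candidate's long axis at an
                # interior point of the anchor, roughly along the anchor's
                # normal there, then slide it in until the masks first touch.
                # This yields a T-shaped clump (one skeleton junction), the
                # configuration the clump splitter is designed for.
                j = int(rng.integers(0, len(masks)))
                sp_a = truths[j].spine
                k = int(rng.integers(int(0.25 * len(sp_a)), int(0.75 * len(sp_a))))
                tang = sp_a[min(k + 3, len(sp_a) - 1)] - sp_a[max(k - 3, 0)]
                tang = tang / (np.linalg.norm(tang) + 1e-9)
                d = np.array([-tang[1], tang[0]]) * rng.choice([-1.0, 1.0])
                jit = rng.uniform(-0.4, 0.4)
                rotj = np.array([[np.cos(jit), -np.sin(jit)], [np.sin(jit), np.cos(jit)]])
                d = rotj @ d
                angle = np.arctan2(d[0], d[1]) + rng.normal(0, 0.15)
                start = sp_a[k] + (length * 0.6 + 25.0) * d
                spine = _transform(spine0, angle, start)
                if not in_bounds(spine, width):
                    continue
                crng = np.random.default_rng(crng_seed)
                mask, gray = _render_band(
                    spine, width, cens, spec.constriction_depth,
                    spec.constriction_lightening, spec.foreground_gray[0],
                    spec.foreground_gray[1], spec.edge_lightening, (H, W), crng,
                )
                others = occupied & ~masks[j]
                hit = None
                for t in range(1, int(length + 40)):
                    pos = start - t * d
                    dr, dc = int(round(pos[0] - start[0])), int(round(pos[1] - start[1]))
                    sh = _shift_mask(mask, dr, dc)
                    if sh is None or not in_bounds(spine + [dr, dc], width):
                        break
                    if (_dilate(sh, 2) & others).any():
                        break  # would clip a third chromosome
                    if (sh & masks[j]).any():
                        break  # overshot into overlap: previous step failed too
                    if (_dilate(sh, 1) & masks[j]).any():
                        hit = (dr, dc)
                        break
                if hit is None:
                    continue
                # verify T-geometry: contact must sit on the anchor's side
                # (interior arc) and at the candidate's end, transversally —
                # end-to-end unions would read as one long chromosome
                sh = _shift_mask(mask, *hit)
                contact = np.argwhere(_dilate(sh, 1) & masks[j]).mean(axis=0)
                fr_a = _nearest_frac(sp_a, contact)
                cand_spine = spine + np.array(hit, dtype=float)
                fr_c = _nearest_frac(cand_spine, contact)
                ka = int(round(fr_a * (len(sp_a) - 1)))
                ta = sp_a[min(ka + 3, len(sp_a) - 1)] - sp_a[max(ka - 3, 0)]
                ta = ta / (np.linalg.norm(ta) + 1e-9)
                if not (0.15 <= fr_a <= 0.85) or min(fr_c, 1 - fr_c) > 0.2:
                    continue
                if abs(float(np.dot(ta, d))) > np.cos(np.deg2rad(50.0)):
                    continue
                dr, dc = hit
                spine = spine + np.array([dr, dc], dtype=float)
                crng = np.random.default_rng(crng_seed)
                mask, gray = _render_band(
                    spine, width, cens, spec.constriction_depth,
                    spec.constriction_lightening, spec.foreground_gray[0],
                    spec.foreground_gray[1], spec.edge_lightening, (H, W), crng,
                )
                adjacency.append((j, i, "touching"))
            else:
                if mode == "cross":
                    j = int(rng.integers(0, len(masks)))
                    k = int(rng.integers(0, len(truths[j].spine)))
                    offset = truths[j].spine[k] + rng.normal(0, 2.0, size=2)
                else:
                    offset = np.array([
                        rng.uniform(width + 4, H - width - 4),
                        rng.uniform(width + 4, W - width - 4),
                    ])
                spine = _transform(spine0, angle, offset)
                if not in_bounds(spine, width):
                    continue
                crng = np.random.default_rng(crng_seed)
                mask, gray = _render_band(
                    spine, width, cens, spec.constriction_depth,
                    spec.constriction_lightening, spec.foreground_gray[0],
                    spec.foreground_gray[1], spec.edge_lightening, (H, W), crng,
                )
                inter = mask & occupied
                if mode == "free" or not masks:
                    if (_dilate(mask, 2) & occupied).any():
                        continue
                else:  # cross
                    if not inter.any() or inter.sum() > 0.4 * mask.sum():
                        continue
                    partners = {k for k, m in enumerate(masks) if (inter & m).any()}
                    if partners != {j}:
                        continue
                    others = occupied & ~masks[j]
                    if (_dilate(mask, 2) & others).any():
                        continue
                    adjacency.append((j, i, "overlapping"))
            canvas = np.where(mask, np.minimum(canvas, gray), canvas)
            occupied |= mask
            masks.append(mask)
            truths.append(_truth_for(spine, mask, cens))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place chromosome {i} ({modes[i]}) after bounded retries"
            )

    # stain impurities: 1-2 px specks, below any sensible min-area cut
    for _ in range(spec.impurity_count):
        r = int(rng.integers(2, H - 2))
        c = int(rng.integers(2, W - 2))
        if _dilate(occupied, 2)[r, c]:
            continue
        rad = int(rng.integers(1, 3))
        rr, cc = np.mgrid[r - rad:r + rad + 1, c - rad:c + rad + 1]
        keep = (rr - r) ** 2 + (cc - c) ** 2 <= rad**2 - 1
        canvas[rr[keep], cc[keep]] = rng.normal(spec.foreground_gray[0], 10)

    img = MetaphaseImage(
        pixels=np.clip(canvas, 0, 255).astype(np.uint8),
        image_id=f"phantom_{spec.rng_seed}",
    )
    truth = PhantomTruth(
        chromosomes=truths,
        n_dicentrics=sum(1 for t in truths if t.n_centromeres == 2),
        adjacency=adjacency,
    )
    return img, truth


def make_single_chromosome_image(
    n_centromeres: int = 1,
    seed: int = 0,
    spec: PhantomSpec | None = None,
) -> tuple[MetaphaseImage, ChromosomeTruth]:
    """One chromosome on a clean background patch — the unit fixture for
    centerline and centromere benchmarks."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    length = rng.uniform(*spec.length_range)
    width = rng.uniform(*spec.width_range)
    curv = rng.uniform(*spec.curvature_range)
    cens = _sample_centromeres(n_centromeres, rng)
    mask, gray, truth = make_chromosome(
        length, width, curv, cens,
        depth=spec.constriction_depth,
        seed=int(rng.integers(0, 2**31)),
        lightening=spec.constriction_lightening,
        core_gray=spec.foreground_gray[0],
        fg_sigma=spec.foreground_gray[1],
        edge_lightening=spec.edge_lightening,
    )
    H = max(32, mask.shape[0])
    W = max(32, mask.shape[1])
    canvas = np.clip(
        rng.normal(spec.background_gray[0], spec.background_gray[1], size=(H, W)),
        0, 255,
    )
    canvas[: mask.shape[0], : mask.shape[1]][mask] = gray[mask]
    img = MetaphaseImage(np.clip(canvas, 0, 255).astype(np.uint8),
                         image_id=f"single_{seed}")
    full_mask = np.zeros((H, W), dtype=bool)
    full_mask[: mask.shape[0], : mask.shape[1]] = mask
    truth.mask = full_mask
    return img, truth
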