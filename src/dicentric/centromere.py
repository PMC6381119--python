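"""Centromere detection from equivalent-width profiles.

A centromere is the constriction of a chromosome: locally narrower and more
lightly stained. Both cues are combined into a single per-centerline-point
score, the equivalent width

    Y_i = sum_j D_ij**m * G_ij**n ,

where the sum runs over the pixels sampled along the normal to the centerline
at point P_i, D_ij is the distance of sample j from P_i, and G_ij = 255 - M_ij
is the inverted gray value (dark stain -> large G). Only pixels inside the
object mask contribute; the background contributes nothing. With the default
m = n = 1 the score shrinks both when the chromosome narrows and when the
stain lightens, so centromeres appear as local minima of the profile.

Detection then follows a five-step procedure: (1) low-pass filter the
profile; (2) fit a straight trend line and form the difference curve
trend - filtered; (3) differentiate and filter again to localize extrema;
(4) for each local minimum measure the prominences A (to the nearest maximum
on the left) and B (right); (5) accept the minimum as a centromere when
(A > T or B > T) and (A > T/2 and B > T/2). The count classifies the
chromosome: 0 none, 1 monocentric, 2 dicentric, >=3 multicentric.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .centerline import Centerline
from .segmentation import ChromosomeObject

__all__ = [
    "EqWidthParams",
    "WidthProfile",
    "CentromereCall",
    "Classification",
    "CellScore",
    "perpendicular_samples",
    "equivalent_width",
    "build_profile",
    "detect_centromeres",
    "score_cell",
]


class Classification(str, enum.Enum):
    ACENTRIC_LIKE = "acentric_like"
    MONOCENTRIC = "monocentric"
    DICENTRIC = "dicentric"
    MULTICENTRIC = "multicentric"


@dataclass(frozen=True)
class EqWidthParams:
    """Parameters of the equivalent width and its detection.

    m, n : exponents on distance and inverted gray (0**0 := 1).
    T : absolute prominence threshold in equivalent-width units; used when
        ``T_rel`` is None. Calibrated on the synthetic phantom corpus and
        user-overridable.
    T_rel : if set (default), the threshold adapts to each chromosome:
        T_eff = T_rel * median(filtered profile). Equivalent-width units
        scale with band width and stain depth, so a relative threshold keeps
        one calibration valid across small and large chromosomes.
    filter_window : odd moving-average window (points).
    end_margin_frac : fraction of the profile excluded at each end
        (telomere ends taper and ripple spuriously).
    min_separation_frac : accepted minima closer than this fraction of the
        centerline length are merged, keeping the more prominent one.
    use_difference_curve : measure minima/prominences on the difference
        curve instead of the filtered profile.
    """

    m: int = 1
    n: int = 1
    T: float = 1200.0
    T_rel: float | None = 0.45
    filter_window: int = 9
    end_margin_frac: float = 0.15
    min_separation_frac: float = 0.1
    use_difference_curve: bool = False

    def __post_init__(self) -> None:
        if self.m < 0 or self.n < 0:
            raise ValueError("m and n must be non-negative integers")
        if self.filter_window < 3 or self.filter_window % 2 == 0:
            raise ValueError("filter_window must be odd and >= 3")
        if self.T <= 0:
            raise ValueError("threshold T must be positive")


@dataclass
class WidthProfile:
    """Equivalent-width profile along a centerline, with the filtered,
    trend, difference and derivative signals used by the detector."""

    y_raw: np.ndarray
    y_filtered: np.ndarray
    trend_line: tuple[float, float]       # (slope, intercept)
    diff_curve: np.ndarray                # trend - filtered
    diff_deriv: np.ndarray
    centerline: Centerline
    params: EqWidthParams

    def __len__(self) -> int:
        return len(self.y_raw)


@dataclass
class CentromereCall:
    """Accepted centromere minima for one chromosome."""

    indices: list[int]
    prominences: list[tuple[float, float]]   # (A, B) per accepted minimum
    n_centromeres: int
    classification: Classification
    object_id: int = 0

    @property
    def is_dicentric(self) -> bool:
        return self.classification is Classification.DICENTRIC


@dataclass
class CellScore:
    """Per-metaphase aggregation."""

    n_objects: int
    n_dicentrics: int
    n_flagged: int


def perpendicular_samples(
    centerline: Centerline, obj: ChromosomeObject, i: int
) -> list[tuple[float, float]]:
    """Sample (D_ij, G_ij) pairs along the normal at centerline point i.

    Walks the normal from P_i in unit steps in both directions, reading the
    nearest pixel's gray value, and stops on each side at the first step that
    leaves the object mask. D is the Euclidean distance from P_i;
    G = 255 - M. Background pixels never contribute.
    """
    p = centerline.points[i]
    nrm = centerline.normals[i]
    mask, gray = obj.mask, obj.gray_crop
    out: list[tuple[float, float]] = []
    for sign in (-1.0, 1.0):
        t = 0.0 if sign > 0 else 1.0  # center point (t=0) contributes once
        while True:
            q = p + sign * t * nrm
            r, c = int(round(q[0])), int(round(q[1]))
            if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]) or not mask[r, c]:
                break
            out.append((t, 255.0 - float(gray[r, c])))
            t += 1.0
    return out


def equivalent_width(samples: list[tuple[float, float]], m: int = 1, n: int = 1) -> float:
    """Y = sum_j D_j**m * G_j**n over the perpendicular samples, with
    0**0 := 1 so m=0 or n=0 degenerate cleanly (m=n=0 counts pixels, i.e.
    the plain geometric width)."""
    total = 0.0
    for d, g in samples:
        dm = 1.0 if m == 0 else d**m
        gn = 1.0 if n == 0 else g**n
        total += dm * gn
    return total


def _lowpass(x: np.ndarray, window: int) -> np.ndarray:
    return uniform_filter1d(x.astype(float), size=window, mode="reflect")


def build_profile(
    obj: ChromosomeObject, centerline: Centerline, params: EqWidthParams | None = None
) -> WidthProfile:
    """Equivalent-width profile plus the filtered / trend / difference /
    derivative signals of the detection procedure."""
    params = params or EqWidthParams()
    if len(centerline) < params.filter_window:
        raise ValueError("centerline shorter than the filter window")
    y_raw = np.array(
        [
            equivalent_width(perpendicular_samples(centerline, obj, i), params.m, params.n)
            for i in range(len(centerline))
        ]
    )
    y_filtered = _lowpass(y_raw, params.filter_window)
    x = np.arange(len(y_filtered), dtype=float)
    slope, intercept = np.polyfit(x, y_filtered, 1)
    trend = slope * x + intercept
    diff_curve = trend - y_filtered
    diff_deriv = _lowpass(np.gradient(diff_curve), params.filter_window)
    return WidthProfile(
        y_raw=y_raw,
        y_filtered=y_filtered,
        trend_line=(float(slope), float(intercept)),
        diff_curve=diff_curve,
        diff_deriv=diff_deriv,
        centerline=centerline,
        params=params,
    )


def _local_minima(sig: np.ndarray, lo: int, hi: int) -> list[int]:
    """Interior local minima of ``sig`` restricted to [lo, hi]; plateaus
    count once, at their midpoint."""
    mins: list[int] = []
    n = len(sig)
    i = 1
    while i < n - 1:
        if sig[i] < sig[i - 1]:
            j = i
            while j + 1 < n and sig[j + 1] == sig[i]:
                j += 1
            if j + 1 < n and sig[j + 1] > sig[i]:
                mid = (i + j) // 2
                if lo <= mid <= hi:
                    mins.append(mid)
            i = j + 1
        else:
            i += 1
    return mins


def _side_max(sig: np.ndarray, idx: int, direction: int) -> float:
    """Value of the nearest local maximum of ``sig`` on one side of idx
    (direction -1 = left, +1 = right); the profile end value if none."""
    n = len(sig)
    i = idx + direction
    while 0 < i < n - 1:
        if sig[i] >= sig[i - 1] and sig[i] >= sig[i + 1]:
            return float(sig[i])
        i += direction
    return float(sig[0] if direction < 0 else sig[n - 1])


def detect_centromeres(
    profile: WidthProfile, params: EqWidthParams | None = None
) -> CentromereCall:
    """Apply the prominence rule to the profile's local minima.

    Minima within ``end_margin_frac`` of either end are not candidates.
    For each remaining minimum, A and B are the height differences to the
    nearest local maximum on the left and right; the minimum is a centromere
    iff (A > T or B > T) and (A > T/2 and B > T/2). Accepted minima closer
    than ``min_separation_frac`` of the profile length are merged, keeping
    the more prominent (larger min(A, B)) one.
    """
    params = params or profile.params
    # constrictions are minima of the filtered profile = maxima of the
    # difference curve; the configurable switch measures on either signal
    sig = -profile.diff_curve if params.use_difference_curve else profile.y_filtered
    n = len(sig)
    margin = int(round(params.end_margin_frac * n))
    lo, hi = margin, n - 1 - margin
    if params.T_rel is not None:
        T_eff = params.T_rel * float(np.median(profile.y_filtered))
    else:
        T_eff = params.T
    accepted: list[tuple[int, float, float]] = []
    for idx in _local_minima(sig, lo, hi):
        a = _side_max(sig, idx, -1) - sig[idx]
        b = _side_max(sig, idx, +1) - sig[idx]
        T = T_eff
        if (a > T or b > T) and (a > T / 2 and b > T / 2):
            accepted.append((idx, float(a), float(b)))
    # merge near-duplicates
    min_sep = max(1, int(round(params.min_separation_frac * n)))
    accepted.sort(key=lambda t: t[0])
    merged: list[tuple[int, float, float]] = []
    for cand in accepted:
        if merged and cand[0] - merged[-1][0] < min_sep:
            keep = max(merged[-1], cand, key=lambda t: min(t[1], t[2]))
            merged[-1] = keep
        else:
            merged.append(cand)
    count = len(merged)
    if count == 0:
        cls = Classification.ACENTRIC_LIKE
    elif count == 1:
        cls = Classification.MONOCENTRIC
    elif count == 2:
        cls = Classification.DICENTRIC
    else:
        cls = Classification.MULTICENTRIC
    return CentromereCall(
        indices=[t[0] for t in merged],
        prominences=[(t[1], t[2]) for t in merged],
        n_centromeres=count,
        classification=cls,
    )


def score_cell(
    calls: list[CentromereCall], n_flagged: int = 0, n_objects: int | None = None
) -> CellScore:
    """Aggregate one metaphase: count dicentric calls; clumps left for
    manual review are tallied separately as flagged."""
    n_dic = sum(1 for c in calls if c.is_dicentric)
    return CellScore(
        n_objects=n_objects if n_objects is not None else len(calls),
        n_dicentrics=n_dic,
        n_flagged=n_flagged,
    )
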