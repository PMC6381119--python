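"""End-to-end orchestration: segment -> centerline -> centromere -> dose.

``process_image`` runs the full scoring chain on one metaphase in memory;
``run_pipeline`` maps it over an image directory and writes the standard
outputs (per-object crops + JSON sidecars, a review queue of clumps left for
manual scoring, a per-cell CSV, a cohort dose estimate). ``score_objects``
is the common policy for routing segmented objects:

  * single chromosomes are scored directly;
  * touching clumps are split (clump k-means seeds + watershed regrowth) and
    the pieces scored;
  * overlapping/cross clumps, and clumps whose cores cannot be separated,
    go to the review queue — they are counted as flagged, never guessed.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .centerline import Centerline, extract_centerline
from .centromere import (
    CellScore,
    CentromereCall,
    build_profile,
    detect_centromeres,
    score_cell,
)
from .config import RunConfig
from .dosimetry import confidence_interval
from .io import read_image, write_object_png
from .phantoms import PhantomTruth
from .segmentation import (
    ChromosomeObject,
    ClumpSplitError,
    MetaphaseImage,
    ObjectKind,
    classify_object,
    extract_objects,
    kmeans_cluster_image,
    resegment_clump,
    watershed_grow,
)

logger = logging.getLogger("dicentric")

__all__ = [
    "ScoredObject",
    "ImageResult",
    "score_objects",
    "process_image",
    "run_pipeline",
    "evaluate_against_truth",
]


@dataclass
class ScoredObject:
    """One segmented object with its centromere call (None if unscorable)."""

    obj: ChromosomeObject
    call: CentromereCall | None
    centerline: Centerline | None = None
    from_clump: bool = False
    error: str | None = None

    @property
    def is_dicentric(self) -> bool:
        return self.call is not None and self.call.is_dicentric


@dataclass
class ImageResult:
    image_id: str
    scored: list[ScoredObject]
    review: list[ChromosomeObject]
    cell: CellScore

    def full_mask(self, scored: ScoredObject, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = scored.obj.bbox
        m[r0:r1, c0:c1] = scored.obj.mask
        return m


def score_objects(
    objs: list[ChromosomeObject], cfg: RunConfig
) -> tuple[list[ScoredObject], list[ChromosomeObject]]:
    """Route objects through classification / clump splitting and score each
    resulting single chromosome. Returns (scored singles, review queue)."""
    scored: list[ScoredObject] = []
    review: list[ChromosomeObject] = []
    for obj in objs:
        kind = classify_object(obj, cfg.classifier)
        if kind == ObjectKind.SINGLE:
            scored.append(_score_single(obj, cfg, from_clump=False))
        elif kind == ObjectKind.TOUCHING_CLUMP:
            try:
                seeds = resegment_clump(
                    obj, cfg.kmeans, min_seed_area=max(1, cfg.classifier.min_area_px // 2)
                )
                for piece in watershed_grow(obj, seeds):
                    scored.append(_score_single(piece, cfg, from_clump=True))
            except ClumpSplitError as exc:
                logger.info("clump %d -> review queue (%s)", obj.object_id, exc)
                obj.kind = ObjectKind.OVERLAPPING_CLUMP
                review.append(obj)
        else:
            review.append(obj)
    return scored, review


def _score_single(obj: ChromosomeObject, cfg: RunConfig, from_clump: bool) -> ScoredObject:
    try:
        cline = extract_centerline(obj, cfg.centerline)
        profile = build_profile(obj, cline, cfg.eqwidth)
        call = detect_centromeres(profile, cfg.eqwidth)
        call.object_id = obj.object_id
        return ScoredObject(obj=obj, call=call, centerline=cline, from_clump=from_clump)
    except ValueError as exc:
        logger.warning("object %d unscorable: %s", obj.object_id, exc)
        return ScoredObject(obj=obj, call=None, from_clump=from_clump, error=str(exc))


def process_image(image: MetaphaseImage, cfg: RunConfig | None = None) -> ImageResult:
    """Segment and score one metaphase image."""
    cfg = cfg or RunConfig()
    mask = kmeans_cluster_image(image, cfg.kmeans)
    objs = extract_objects(mask, cfg.classifier.min_area_px, gray=image.pixels)
    scored, review = score_objects(objs, cfg)
    calls = [s.call for s in scored if s.call is not None]
    cell = score_cell(calls, n_flagged=len(review), n_objects=len(scored))
    return ImageResult(image_id=image.image_id, scored=scored, review=review, cell=cell)


def run_pipeline(cfg: RunConfig, input_dir: str | Path = ".") -> dict:
    """Process every image matching ``cfg.input_glob`` under ``input_dir``.

    Writes, under ``cfg.out_dir``: ``objects/<image>/obj_NNN.png`` crops with
    JSON sidecars, ``review_queue/`` crops for manual scoring, ``cells.csv``
    (one row per metaphase), ``dose_estimate.json`` for the cohort, and
    ``run.log``. Returns the run report as a dict. Unreadable images are
    skipped with a logged warning; zero scorable cells is an error.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(cfg.log_level)
    try:
        paths = sorted(Path(input_dir).glob(cfg.input_glob))
        results: list[ImageResult] = []
        rows: list[dict] = []
        skipped = 0
        for path in paths:
            try:
                image = read_image(path)
            except Exception as exc:  # unreadable input file
                logger.warning("skipping %s: %s", path.name, exc)
                skipped += 1
                continue
            res = process_image(image, cfg)
            results.append(res)
            _write_image_outputs(res, out)
            rows.append(
                {
                    "image_id": res.image_id,
                    "n_objects": res.cell.n_objects,
                    "n_dicentrics": res.cell.n_dicentrics,
                    "n_flagged": res.cell.n_flagged,
                }
            )
        if not rows:
            raise RuntimeError("no scorable cells found")
        import pandas as pd

        cells = pd.DataFrame(rows)
        cells.to_csv(out / "cells.csv", index=False, lineterminator="\r\n")
        X = int(cells.n_dicentrics.sum())
        M = len(cells)
        estimate = confidence_interval(X, M, cfg.curve)
        (out / "dose_estimate.json").write_text(
            json.dumps(estimate.as_dict(), indent=2)
        )
        cfg.to_yaml(out / "config_echo.yaml")
        report = {
            "version": __version__,
            "n_images": M,
            "n_skipped": skipped,
            "X": X,
            "dose": estimate.as_dict(),
            "cells_csv": str(out / "cells.csv"),
        }
        logger.info("run complete: %s", report)
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()


def _write_image_outputs(res: ImageResult, out: Path) -> None:
    obj_dir = out / "objects" / res.image_id
    obj_dir.mkdir(parents=True, exist_ok=True)
    review_dir = out / "review_queue"
    for s in res.scored:
        stem = f"obj_{s.obj.object_id:03d}"
        write_object_png(obj_dir / f"{stem}.png", s.obj)
        meta = {
            "object_id": s.obj.object_id,
            "bbox": [int(v) for v in s.obj.bbox],
            "kind": s.obj.kind.value,
            "area_px": int(s.obj.area_px),
            "from_clump": s.from_clump,
        }
        if s.call is not None:
            meta.update(
                n_centromeres=s.call.n_centromeres,
                classification=s.call.classification.value,
                indices=[int(i) for i in s.call.indices],
                prominences=[[float(a), float(b)] for a, b in s.call.prominences],
            )
        else:
            meta["error"] = s.error
        (obj_dir / f"{stem}.json").write_text(json.dumps(meta, indent=2))
    for obj in res.review:
        review_dir.mkdir(parents=True, exist_ok=True)
        stem = f"{res.image_id}_obj_{obj.object_id:03d}"
        write_object_png(review_dir / f"{stem}.png", obj)
        (review_dir / f"{stem}.json").write_text(
            json.dumps(
                {
                    "image_id": res.image_id,
                    "object_id": obj.object_id,
                    "bbox": [int(v) for v in obj.bbox],
                    "kind": obj.kind.value,
                    "area_px": int(obj.area_px),
                },
                indent=2,
            )
        )


def evaluate_against_truth(
    results: list[ImageResult],
    truths: list[PhantomTruth],
    image_shape: tuple[int, int],
    iou_threshold: float = 0.5,
) -> dict:
    """Score dicentric detection against phantom ground truth.

    A detection matches a true dicentric when the object and ground-truth
    masks overlap with IoU >= ``iou_threshold`` and both carry the dicentric
    label. Returns TPR (None when there are no true dicentrics), PPV (None
    when nothing was detected) and the confusion counts.
    """
    tp = fp = fn = 0
    for res, truth in zip(results, truths):
        true_dics = [t for t in truth.chromosomes if t.n_centromeres == 2]
        det = [s for s in res.scored if s.is_dicentric]
        used: set[int] = set()
        for s in det:
            fm = res.full_mask(s, image_shape)
            matched = False
            for k, t in enumerate(true_dics):
                if k in used:
                    continue
                inter = int((t.mask & fm).sum())
                union = int((t.mask | fm).sum())
                if union and inter / union >= iou_threshold:
                    used.add(k)
                    matched = True
                    break
            if matched:
                tp += 1
            else:
                fp += 1
        fn += len(true_dics) - len(used)
    tpr = tp / (tp + fn) if (tp + fn) > 0 else None
    ppv = tp / (tp + fp) if (tp + fp) > 0 else None
    return {"TPR": tpr, "PPV": ppv, "tp": tp, "fp": fp, "fn": fn}
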