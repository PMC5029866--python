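"""Segment assembly and spurious-region filtering.

Boundary extraction is deliberately permissive: every seed yields a
contour, including seeds raised by ink stains or other bright
artifacts.  Because genuine nuclei are dark on the PCA grayscale while
stain artifacts are bright, a segment whose mean interior intensity
exceeds a threshold (default 0.6 on the [0, 1] scale) is discarded as a
false alarm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from skimage.draw import polygon2mask

from .boundary_mrf import BoundaryContour
from .evaluation import dice_coefficient

__all__ = [
    "NucleusSegment",
    "rasterize_contour",
    "make_segment",
    "filter_spurious",
    "deduplicate",
    "segments_to_label_mask",
]


@dataclass(frozen=True)
class NucleusSegment:
    """A detected nucleus: contour, filled mask, and summary statistics."""

    id: int
    contour: BoundaryContour
    mask: np.ndarray  # boolean (H, W)
    mean_intensity: float
    area: int


def rasterize_contour(contour: BoundaryContour, shape: tuple[int, int]) -> np.ndarray:
    """Fill a closed boundary polygon into a boolean pixel mask.

    A pixel belongs to the mask when its center lies inside the polygon
    (even-odd rule).  A degenerate polygon (zero area) yields an empty
    mask with a warning.
    """
    verts = np.asarray(contour.vertices, dtype=np.float64)
    if len(verts) < 3 or _shoelace_area(verts) == 0.0:
        warnings.warn("degenerate boundary polygon; empty mask", stacklevel=2)
        return np.zeros(shape, dtype=bool)
    return polygon2mask(shape, verts)


def _shoelace_area(vertices: np.ndarray) -> float:
    r, c = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(float(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1))))


def make_segment(
    seg_id: int, contour: BoundaryContour, gray: np.ndarray
) -> NucleusSegment | None:
    """Rasterize a contour and attach area / mean-intensity statistics.

    Returns None for degenerate contours whose mask is empty.
    """
    mask = rasterize_contour(contour, gray.shape)
    area = int(mask.sum())
    if area == 0:
        return None
    return NucleusSegment(
        id=seg_id,
        contour=contour,
        mask=mask,
        mean_intensity=float(gray[mask].mean()),
        area=area,
    )


def filter_spurious(
    segments: list[NucleusSegment],
    gray: np.ndarray,
    mean_threshold: float = 0.6,
) -> list[NucleusSegment]:
    """Drop segments whose mean interior intensity exceeds the threshold.

    Nuclei are dark on the PCA grayscale; ink stains and other artifacts
    have very high mean intensity and are rejected.  Survivors are
    relabeled densely 1..n.
    """
    kept = [s for s in segments if s.mean_intensity <= mean_threshold]
    return [replace(s, id=i + 1) for i, s in enumerate(kept)]


def deduplicate(
    segments: list[NucleusSegment], dice_threshold: float = 0.8
) -> list[NucleusSegment]:
    """Optional pass removing near-duplicate detections.

    When a segment's seed lies inside another contour's mask and the two
    masks overlap with Dice above ``dice_threshold``, only the segment
    with the lower mean intensity (the more nucleus-like one) survives.
    Off by default in the pipeline.
    """
    discard: set[int] = set()
    for i, a in enumerate(segments):
        for j in range(i + 1, len(segments)):
            b = segments[j]
            if i in discard or j in discard:
                continue
            seed_inside = (
                b.mask[a.contour.seed.row, a.contour.seed.col]
                or a.mask[b.contour.seed.row, b.contour.seed.col]
            )
            if seed_inside and dice_coefficient(a.mask, b.mask) > dice_threshold:
                discard.add(j if a.mean_intensity <= b.mean_intensity else i)
    kept = [s for i, s in enumerate(segments) if i not in discard]
    return [replace(s, id=i + 1) for i, s in enumerate(kept)]


def segments_to_label_mask(
    segments: list[NucleusSegment], shape: tuple[int, int]
) -> np.ndarray:
    """Paint segments into a uint16 label image (later ids overwrite)."""
    out = np.zeros(shape, dtype=np.uint16)
    for seg in segments:
        out[seg.mask] = seg.id
    return out
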