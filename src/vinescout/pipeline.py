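"""Zone extraction, overlap patching, detection dispatch and reassembly.

This module owns the deterministic middle of the five-stage detection
pipeline. Stage 1 (foreground referring segmentation) and stage 4
(per-patch instance segmentation) are delegated to pluggable backends;
here live stage 2 (grape-zone extraction from the foreground mask),
stage 3 (decomposition of each zone into overlapping fixed-size patches)
and stage 5 (translation of patch-local polygons back to image
coordinates, de-duplication of detections that appear in several patches,
and per-image bunch counting).

De-duplication builds an overlap graph over rasterized instance masks:
two instances are merged when their IoU reaches ``merge_iou`` or when the
intersection covers at least ``containment`` of the smaller mask (a
clipped duplicate of a bunch straddling a patch seam has low IoU against
the full detection but near-total containment). Connected components of
that graph become single instances whose confidence is the maximum over
members. Provided the patch overlap exceeds the largest bunch diameter,
every bunch appears whole in at least one patch, so clipped fragments
always attach to a full detection and the reassembled count and fused
mask reproduce the ground truth exactly.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from shapely.geometry import box
from shapely.ops import unary_union
from skimage import measure

from ._geometry import clean_polygon, rasterize_polygon
from .backends import (
    BackendError,
    ForegroundBackend,
    InstanceBackend,
    InstanceShape,
)

Rect = tuple[int, int, int, int]  # half-open (x0, y0, x1, y1)


@dataclasses.dataclass(frozen=True)
class Zone:
    """A rectangular crop around one foreground component."""

    rect: Rect
    source_component_area: int

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.rect
        if x1 <= x0 or y1 <= y0:
            raise ValueError(f"empty zone rect {self.rect}")


@dataclasses.dataclass(frozen=True)
class PatchGrid:
    """Deterministic overlapping decomposition of a rectangle.

    Anchors advance by ``patch_size - overlap``; the final anchor per axis
    is clamped so the last patch ends flush at the far edge. For rects
    smaller than ``patch_size`` a single patch anchored at the rect origin
    covers (and overhangs) the rect; overhanging pixels are reflect-padded
    at dispatch time rather than rescaled, preserving pixel scale.
    """

    patch_size: int
    overlap: int
    offsets: tuple[tuple[int, int], ...]
    parent_rect: Rect

    @property
    def stride(self) -> int:
        return self.patch_size - self.overlap

    def patch_rect(self, index: int) -> Rect:
        x, y = self.offsets[index]
        return (x, y, x + self.patch_size, y + self.patch_size)

    def __len__(self) -> int:
        return len(self.offsets)


@dataclasses.dataclass
class DetectionSet:
    """Image-level detections after reassembly: instances, mask, count."""

    image_id: str
    instances: list[InstanceShape]
    fused_mask: np.ndarray
    count: int


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    query: str = "the foreground vine row"
    patch_size: int = 640
    overlap: int = 128
    merge_iou: float = 0.3
    containment: float = 0.8
    min_zone_area: int = 2000
    zone_margin: int = 16
    foreground_gate: float = 0.5


def extract_zones(mask: np.ndarray, min_area: int = 2000, margin: int = 16) -> list[Zone]:
    """One zone per foreground connected component with area >= min_area.

    The zone rect is the component bounding box dilated by ``margin`` and
    clipped to the image. An empty mask yields an empty list.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    zones: list[Zone] = []
    labels = measure.label(mask, connectivity=2)
    for prop in measure.regionprops(labels):
        if prop.area < min_area:
            continue
        r0, c0, r1, c1 = prop.bbox
        rect = (
            max(c0 - margin, 0),
            max(r0 - margin, 0),
            min(c1 + margin, w),
            min(r1 + margin, h),
        )
        zones.append(Zone(rect=rect, source_component_area=int(prop.area)))
    zones.sort(key=lambda z: (z.rect[1], z.rect[0]))
    return zones


def _axis_anchors(start: int, stop: int, patch: int, stride: int) -> list[int]:
    extent = stop - start
    if extent <= patch:
        return [start]
    anchors = list(range(start, stop - patch, stride))
    last = stop - patch
    if anchors[-1] != last:
        anchors.append(last)
    return anchors


def make_patch_grid(rect: Rect, patch_size: int = 640, overlap: int = 128) -> PatchGrid:
    """Cover ``rect`` with overlapping ``patch_size`` squares.

    Anchors lie at multiples of the stride from the rect origin, with the
    final row/column clamped flush to the far edge so coverage is exact.
    """
    if not 0 <= overlap < patch_size:
        raise ValueError(f"need 0 <= overlap < patch_size, got {overlap} vs {patch_size}")
    x0, y0, x1, y1 = rect
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"empty rect {rect}")
    stride = patch_size - overlap
    xs = _axis_anchors(x0, x1, patch_size, stride)
    ys = _axis_anchors(y0, y1, patch_size, stride)
    offsets = tuple((x, y) for y in ys for x in xs)
    return PatchGrid(patch_size=patch_size, overlap=overlap, offsets=offsets, parent_rect=rect)


def extract_patch(image: np.ndarray, grid: PatchGrid, index: int) -> np.ndarray:
    """Pixel content of one patch, reflect-padded where it overhangs."""
    x0, y0, x1, y1 = grid.patch_rect(index)
    h, w = image.shape[:2]
    cx1, cy1 = min(x1, w), min(y1, h)
    patch = image[y0:cy1, x0:cx1]
    pad_y = (y1 - y0) - patch.shape[0]
    pad_x = (x1 - x0) - patch.shape[1]
    if pad_y or pad_x:
        pad = [(0, pad_y), (0, pad_x)] + [(0, 0)] * (image.ndim - 2)
        patch = np.pad(patch, pad, mode="reflect")
    return patch


def _merge_instances(
    instances: list[InstanceShape],
    image_shape: tuple[int, int],
    merge_iou: float,
    containment: float,
) -> tuple[list[InstanceShape], list[np.ndarray]]:
    """Union-find merge over the mask-overlap graph.

    Returns merged instances and their member-union masks (the fused mask
    of a merged instance is the union of its members' rasterizations, so
    reassembly is bit-faithful to the input pieces).
    """
    h, w = image_shape
    masks = [inst.to_mask(h, w) for inst in instances]
    areas = [int(m.sum()) for m in masks]
    n = len(instances)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    bounds = [inst.polygon.bounds for inst in instances]
    for i in range(n):
        if areas[i] == 0:
            continue
        for j in range(i + 1, n):
            if areas[j] == 0:
                continue
            bi, bj = bounds[i], bounds[j]
            if bi[2] < bj[0] or bj[2] < bi[0] or bi[3] < bj[1] or bj[3] < bi[1]:
                continue
            inter = int(np.count_nonzero(masks[i] & masks[j]))
            if inter == 0:
                continue
            iou = inter / (areas[i] + areas[j] - inter)
            cont = inter / min(areas[i], areas[j])
            if iou >= merge_iou or cont >= containment:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        if areas[i] == 0:
            continue
        groups.setdefault(find(i), []).append(i)

    merged: list[InstanceShape] = []
    merged_masks: list[np.ndarray] = []
    for members in groups.values():
        geom = clean_polygon(unary_union([instances[i].polygon for i in members]))
        if geom.geom_type == "MultiPolygon":
            geom = max(geom.geoms, key=lambda p: p.area)
        conf = max(instances[i].confidence for i in members)
        merged.append(
            InstanceShape(
                polygon=geom,
                confidence=conf,
                class_label=instances[members[0]].class_label,
            )
        )
        gm = np.zeros((h, w), dtype=bool)
        for i in members:
            gm |= masks[i]
        merged_masks.append(gm)
    order = sorted(
        range(len(merged)),
        key=lambda k: (merged[k].polygon.bounds[1], merged[k].polygon.bounds[0]),
    )
    return [merged[k] for k in order], [merged_masks[k] for k in order]


def reassemble(
    per_patch: Sequence[Sequence[InstanceShape]],
    grid: PatchGrid,
    image_shape: tuple[int, int],
    merge_iou: float = 0.3,
    containment: float = 0.8,
    image_id: str = "",
) -> DetectionSet:
    """Translate patch-local instances to image coordinates and de-duplicate."""
    if len(per_patch) != len(grid):
        raise ValueError(
            f"{len(per_patch)} instance lists for {len(grid)} grid patches"
        )
    placed: list[InstanceShape] = []
    for idx, instances in enumerate(per_patch):
        x, y = grid.offsets[idx]
        for inst in instances:
            moved = inst.translated(x, y)
            placed.append(dataclasses.replace(moved, source_patch=idx))
    merged, masks = _merge_instances(placed, image_shape, merge_iou, containment)
    fused = np.zeros(image_shape, dtype=bool)
    for m in masks:
        fused |= m
    return DetectionSet(
        image_id=image_id, instances=merged, fused_mask=fused, count=len(merged)
    )


def run_pipeline(
    image: np.ndarray,
    foreground: ForegroundBackend,
    detector: InstanceBackend,
    config: PipelineConfig = PipelineConfig(),
    image_id: str = "",
) -> DetectionSet:
    """Full composition: refer_segment -> zones -> patches -> detect -> reassemble.

    Detections are additionally gated by the stage-1 foreground mask: an
    instance with less than ``foreground_gate`` of its area inside the
    mask is a background-row detection and is dropped, so only the
    foreground vine row contributes to the count.
    """
    h, w = image.shape[:2]
    try:
        fg = foreground.refer_segment(image, config.query)
    except BackendError as exc:
        raise BackendError(f"stage 1 (referring segmentation): {exc}") from exc

    zones = extract_zones(fg, min_area=config.min_zone_area, margin=config.zone_margin)
    collected: list[InstanceShape] = []
    for zone in zones:
        grid = make_patch_grid(zone.rect, config.patch_size, config.overlap)
        per_patch: list[list[InstanceShape]] = []
        for idx in range(len(grid)):
            patch = extract_patch(image, grid, idx)
            try:
                found = detector.detect_instances(patch)
            except BackendError as exc:
                raise BackendError(
                    f"stage 4 (instance segmentation, patch {idx}): {exc}"
                ) from exc
            # keep only detections inside the un-padded patch extent
            x0, y0, x1, y1 = grid.patch_rect(idx)
            vx1, vy1 = min(x1, w) - x0, min(y1, h) - y0
            valid = box(0.0, 0.0, float(vx1), float(vy1))
            kept = []
            for inst in found:
                clipped = clean_polygon(inst.polygon.intersection(valid))
                if clipped.is_empty or clipped.area <= 0:
                    continue
                if clipped.geom_type == "MultiPolygon":
                    clipped = max(clipped.geoms, key=lambda p: p.area)
                kept.append(dataclasses.replace(inst, polygon=clipped))
            per_patch.append(kept)
        part = reassemble(
            per_patch,
            grid,
            (h, w),
            merge_iou=config.merge_iou,
            containment=config.containment,
        )
        collected.extend(part.instances)

    # cross-zone de-duplication + foreground gating
    merged, masks = _merge_instances(
        collected, (h, w), config.merge_iou, config.containment
    )
    gated_instances: list[InstanceShape] = []
    fused = np.zeros((h, w), dtype=bool)
    for inst, m in zip(merged, masks):
        area = int(m.sum())
        if area == 0:
            continue
        inside = int(np.count_nonzero(m & fg))
        if inside / area < config.foreground_gate:
            continue
        gated_instances.append(inst)
        fused |= m
    return DetectionSet(
        image_id=image_id,
        instances=gated_instances,
        fused_mask=fused,
        count=len(gated_instances),
    )
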