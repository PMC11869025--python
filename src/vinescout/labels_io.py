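"""Label preprocessing: CVAT-MOTS annotations to YOLO-seg training labels.

Covers the whole annotation chain used to turn per-pixel video-frame
annotations into segmentation-training labels: reading/writing the MOTS
txt convention (one line per object: frame, object id, class id, raster
dims, COCO-style compressed RLE mask), percentile contrast stretching,
mask-to-polygon conversion in two YOLO-seg label dialects, patch-aware
label splitting, seeded geometric augmentation, and a group-aware
train/validation split.

Two label dialects are supported because tooling differs on the line
layout:

* ``"bbox+polygon"`` — ``<class> <cx> <cy> <w> <h> <x1> <y1> ...`` with a
  normalized tight bounding box preceding the polygon;
* ``"polygon"`` — the common ``<class> <x1> <y1> ...`` layout.

All coordinates are normalized to [0, 1] and written with 6 decimals.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Callable, Hashable, Iterable, Sequence

import numpy as np
from shapely import affinity
from shapely.geometry import Polygon, box

from ._geometry import clean_polygon, polygon_from_mask

DIALECTS = ("bbox+polygon", "polygon")


class MotsParseError(ValueError):
    """A MOTS line failed to parse; message carries file line number."""


# ---------------------------------------------------------------------------
# COCO-style compressed RLE (the string form used by MOTS txt files)
#
# Counts are column-major run lengths starting with the background run;
# each count (delta-coded from the second-previous count onward) is packed
# little-endian in 5-bit signed groups, each group stored as one printable
# character (value + 48, bit 0x20 = continuation).


def rle_encode(mask: np.ndarray) -> str:
    mask = np.asarray(mask, dtype=bool)
    flat = mask.T.ravel()  # column-major
    counts: list[int] = []
    prev = False
    run = 0
    for bit in flat:
        if bit == prev:
            run += 1
        else:
            counts.append(run)
            prev = bit
            run = 1
    counts.append(run)
    chars: list[str] = []
    for i, c in enumerate(counts):
        x = c - counts[i - 2] if i > 2 else c
        more = True
        while more:
            chunk = x & 0x1F
            x >>= 5
            more = (x != -1) if (chunk & 0x10) else (x != 0)
            if more:
                chunk |= 0x20
            chars.append(chr(chunk + 48))
    return "".join(chars)


def rle_decode(rle: str, height: int, width: int) -> np.ndarray:
    counts: list[int] = []
    pos = 0
    while pos < len(rle):
        x = 0
        shift = 0
        more = True
        while more:
            if pos >= len(rle):
                raise MotsParseError("truncated RLE string")
            chunk = ord(rle[pos]) - 48
            pos += 1
            x |= (chunk & 0x1F) << shift
            more = bool(chunk & 0x20)
            if not more and (chunk & 0x10):
                x |= -1 << (shift + 5)  # sign-extend
            shift += 5
        if len(counts) > 2:
            x += counts[-2]
        counts.append(x)
    total = sum(counts)
    if total != height * width:
        raise MotsParseError(
            f"RLE decodes to {total} pixels, expected {height * width}"
        )
    flat = np.zeros(total, dtype=bool)
    idx = 0
    value = False
    for c in counts:
        if value:
            flat[idx : idx + c] = True
        idx += c
        value = not value
    return flat.reshape((width, height)).T


@dataclasses.dataclass
class MotsAnnotation:
    """One per-frame, per-object RLE-encoded instance mask."""

    frame_id: int
    object_id: int
    class_id: int
    height: int
    width: int
    rle: str

    def decode(self) -> np.ndarray:
        return rle_decode(self.rle, self.height, self.width)

    @classmethod
    def from_mask(
        cls, mask: np.ndarray, frame_id: int, object_id: int, class_id: int = 1
    ) -> "MotsAnnotation":
        h, w = mask.shape
        return cls(frame_id, object_id, class_id, h, w, rle_encode(mask))


def read_mots(path: Path | str) -> list[MotsAnnotation]:
    """Parse a MOTS txt file: ``frame obj_id class_id height width rle``."""
    out: list[MotsAnnotation] = []
    seen: set[tuple[int, int]] = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 6:
            raise MotsParseError(f"line {lineno}: expected 6 fields, got {len(parts)}")
        try:
            frame, obj, cls_, h, w = (int(p) for p in parts[:5])
        except ValueError as exc:
            raise MotsParseError(f"line {lineno}: non-integer header field") from exc
        ann = MotsAnnotation(frame, obj, cls_, h, w, parts[5])
        try:
            ann.decode()
        except MotsParseError as exc:
            raise MotsParseError(f"line {lineno} (frame {frame}): {exc}") from exc
        if (frame, obj) in seen:
            raise MotsParseError(
                f"line {lineno}: duplicate object id {obj} in frame {frame}"
            )
        seen.add((frame, obj))
        out.append(ann)
    return out


def write_mots(annotations: Iterable[MotsAnnotation], path: Path | str) -> None:
    lines = [
        f"{a.frame_id} {a.object_id} {a.class_id} {a.height} {a.width} {a.rle}"
        for a in annotations
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# grayscale adjustment


def adjust_grayscale(
    image: np.ndarray, low_pct: float = 1.0, high_pct: float = 99.0
) -> np.ndarray:
    """Percentile contrast stretch.

    The ``low_pct``/``high_pct`` percentiles of the luminance histogram are
    mapped linearly to [0, 255] (one map applied to every channel, so hue
    is preserved), clipped. A constant image comes back unchanged.
    """
    if not 0 <= low_pct < high_pct <= 100:
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    image = np.asarray(image)
    if image.ndim == 3:
        lum = image[..., :3].astype(float).mean(axis=-1)
    else:
        lum = image.astype(float)
    lo, hi = np.percentile(lum, [low_pct, high_pct])
    if hi <= lo:
        return image.copy()
    stretched = (image.astype(float) - lo) * (255.0 / (hi - lo))
    return np.clip(np.rint(stretched), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# YOLO-seg labels


@dataclasses.dataclass
class YoloSegLabel:
    """One instance label, coordinates normalized to the image dims."""

    class_id: int
    bbox: tuple[float, float, float, float]  # (cx, cy, w, h)
    polygon: list[tuple[float, float]]

    def __post_init__(self) -> None:
        coords = list(self.bbox) + [c for xy in self.polygon for c in xy]
        if any(c < -1e-6 or c > 1 + 1e-6 for c in coords):
            raise ValueError("label coordinates must be normalized to [0, 1]")

    def to_polygon(self, width: float, height: float) -> Polygon:
        return Polygon([(x * width, y * height) for x, y in self.polygon])


def _bbox_of(polygon: Sequence[tuple[float, float]]) -> tuple[float, float, float, float]:
    xs = [p[0] for p in polygon]
    ys = [p[1] for p in polygon]
    x0, x1, y0, y1 = min(xs), max(xs), min(ys), max(ys)
    return ((x0 + x1) / 2, (y0 + y1) / 2, x1 - x0, y1 - y0)


def mask_to_label(
    source: np.ndarray | Polygon,
    image_size: tuple[int, int],
    class_id: int = 0,
    simplify_tol: float = 1.0,
) -> YoloSegLabel | None:
    """Convert a binary mask (or pixel-space polygon) into a normalized label.

    For masks the largest outer contour is extracted and Douglas-Peucker
    simplified; an empty mask returns None (caller skips with a warning).
    """
    height, width = image_size
    if isinstance(source, np.ndarray):
        poly = polygon_from_mask(source, simplify_tol=simplify_tol)
        if poly is None:
            return None
    else:
        poly = clean_polygon(source)
        if poly.is_empty or poly.area <= 0:
            return None
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda p: p.area)
    norm = [
        (min(max(x / width, 0.0), 1.0), min(max(y / height, 0.0), 1.0))
        for x, y in poly.exterior.coords[:-1]
    ]
    return YoloSegLabel(class_id=class_id, bbox=_bbox_of(norm), polygon=norm)


def write_labels(
    labels: Iterable[YoloSegLabel], path: Path | str, dialect: str = "bbox+polygon"
) -> None:
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    lines = []
    for lab in labels:
        fields = [str(lab.class_id)]
        if dialect == "bbox+polygon":
            fields += [f"{v:.6f}" for v in lab.bbox]
        fields += [f"{c:.6f}" for xy in lab.polygon for c in xy]
        lines.append(" ".join(fields))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_labels(path: Path | str, dialect: str = "bbox+polygon") -> list[YoloSegLabel]:
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    out: list[YoloSegLabel] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        parts = raw.split()
        cls_ = int(parts[0])
        vals = [float(p) for p in parts[1:]]
        if dialect == "bbox+polygon":
            if len(vals) < 10 or len(vals) % 2 != 0:
                raise ValueError(f"line {lineno}: malformed bbox+polygon label")
            bbox = tuple(vals[:4])
            coords = vals[4:]
        else:
            if len(vals) < 6 or len(vals) % 2 != 0:
                raise ValueError(f"line {lineno}: malformed polygon label")
            coords = vals
            bbox = None
        polygon = list(zip(coords[::2], coords[1::2]))
        if bbox is None:
            bbox = _bbox_of(polygon)
        out.append(YoloSegLabel(class_id=cls_, bbox=bbox, polygon=polygon))
    return out


# ---------------------------------------------------------------------------
# patch-aware label splitting


def split_labels_to_patches(
    polygons: Sequence[tuple[int, Polygon]],
    grid,
    min_visible_fraction: float = 0.1,
) -> dict[int, list[YoloSegLabel]]:
    """Clip image-coordinate instance polygons into each patch of a grid.

    Each polygon is intersected with every patch rectangle; pieces whose
    area falls below ``min_visible_fraction`` of the original instance are
    dropped (slivers teach a detector nothing), the rest are re-normalized
    to patch-local coordinates. Returns {patch index: labels}.
    """
    out: dict[int, list[YoloSegLabel]] = {i: [] for i in range(len(grid))}
    for class_id, poly in polygons:
        poly = clean_polygon(poly)
        if poly.is_empty or poly.area <= 0:
            continue
        for idx in range(len(grid)):
            x0, y0, x1, y1 = grid.patch_rect(idx)
            piece = clean_polygon(poly.intersection(box(x0, y0, x1, y1)))
            if piece.is_empty or piece.area < min_visible_fraction * poly.area:
                continue
            if piece.geom_type == "MultiPolygon":
                piece = max(piece.geoms, key=lambda p: p.area)
            local = affinity.translate(piece, xoff=-x0, yoff=-y0)
            label = mask_to_label(
                local, (grid.patch_size, grid.patch_size), class_id=class_id,
                simplify_tol=0.0,
            )
            if label is not None:
                out[idx].append(label)
    return out


# ---------------------------------------------------------------------------
# augmentation

SUPPORTED_OPS = ("hflip", "vflip", "rotate", "scale")


def _transform_polygons(
    polygons: Sequence[Polygon], fn: Callable[[float, float], tuple[float, float]]
) -> list[Polygon]:
    return [
        Polygon([fn(x, y) for x, y in p.exterior.coords[:-1]]) for p in polygons
    ]


def augment(
    image: np.ndarray,
    polygons: Sequence[Polygon],
    ops: dict,
    seed: int,
) -> tuple[np.ndarray, list[Polygon], list[str]]:
    """Seeded geometric augmentation applied identically to pixels and labels.

    ``ops`` maps op name to its parameter: ``hflip``/``vflip`` -> apply
    probability; ``rotate`` -> list of quarter-turn angles (degrees,
    clockwise, multiples of 90) to choose from; ``scale`` -> (lo, hi)
    factor range. Returns the transformed image, polygons, and the record
    of applied operations. Instance count is never changed.
    """
    unknown = set(ops) - set(SUPPORTED_OPS)
    if unknown:
        raise ValueError(f"unsupported augmentation ops: {sorted(unknown)}")
    from skimage import transform as sktf

    rng = np.random.default_rng(seed)
    img = np.asarray(image)
    polys = [Polygon(p.exterior.coords) for p in polygons]
    applied: list[str] = []

    if "hflip" in ops and rng.random() < float(ops["hflip"]):
        w = img.shape[1]
        img = img[:, ::-1].copy()
        polys = _transform_polygons(polys, lambda x, y: (w - x, y))
        applied.append("hflip")
    if "vflip" in ops and rng.random() < float(ops["vflip"]):
        h = img.shape[0]
        img = img[::-1].copy()
        polys = _transform_polygons(polys, lambda x, y: (x, h - y))
        applied.append("vflip")
    if "rotate" in ops:
        angles = list(ops["rotate"])
        if any(a % 90 != 0 for a in angles):
            raise ValueError("rotate supports quarter-turn angles only")
        angle = int(rng.choice(angles)) % 360
        for _ in range(angle // 90):
            h = img.shape[0]
            img = np.rot90(img, k=-1).copy()  # one clockwise quarter turn
            polys = _transform_polygons(polys, lambda x, y, h=h: (h - y, x))
        if angle:
            applied.append(f"rotate{angle}")
    if "scale" in ops:
        lo, hi = ops["scale"]
        factor = float(rng.uniform(lo, hi))
        channel_axis = 2 if img.ndim == 3 else None
        img = sktf.rescale(
            img, factor, order=1, preserve_range=True, anti_aliasing=factor < 1,
            channel_axis=channel_axis,
        ).astype(image.dtype)
        polys = _transform_polygons(polys, lambda x, y: (x * factor, y * factor))
        applied.append(f"scale{factor:.3f}")
    return img, polys, applied


# ---------------------------------------------------------------------------
# dataset split


def split_dataset(
    items: Sequence,
    train_fraction: float = 0.7,
    seed: int = 0,
    key: Callable[[object], Hashable] | None = None,
) -> tuple[list, list]:
    """Group-aware seeded train/validation split.

    Items sharing a group key (e.g. the source video of a frame) never
    span the split. Groups are shuffled with the seed; the first
    ``round(train_fraction * n_groups)`` groups (clamped so both sides are
    non-empty) form the training set.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    key = key or (lambda item: item)
    groups: dict[Hashable, list] = {}
    for item in items:
        groups.setdefault(key(item), []).append(item)
    names = sorted(groups, key=repr)
    if len(names) < 2:
        raise ValueError("need at least 2 groups to split")
    rng = np.random.default_rng(seed)
    order = [names[i] for i in rng.permutation(len(names))]
    n_train = int(round(train_fraction * len(order)))
    n_train = min(max(n_train, 1), len(order) - 1)
    train_groups = set(order[:n_train])
    train = [it for g in order[:n_train] for it in groups[g]]
    val = [it for g in order[n_train:] for it in groups[g]]
    assert not train_groups & set(order[n_train:])
    return train, val
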