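"""Pluggable segmentation backends for the two neural stages of the pipeline.

The detection pipeline delegates two jobs to external models: stage 1,
referring segmentation of the foreground vine row (the paper-scale system
uses a vision-language model queried with free text), and stage 4,
per-patch instance segmentation of grape bunches. Both are consumed here
purely through their output contract — a boolean foreground mask and a
list of scored polygons — so heavyweight networks can be swapped in via
command-line adapters while the deterministic reference backends keep the
whole pipeline testable on a desk.

Reference backends:

* :class:`LuminanceForeground` — Otsu luminance threshold plus retention of
  the dominant contiguous bright band. It succeeds when the foreground row
  is rendered in focus and brighter than background rows, which is exactly
  the contrast the synthetic scenes construct.
* :class:`HueBlobDetector` — hue-window threshold for grape-colored pixels,
  connected components, minimum-area filter and contour extraction. Its
  confidence score (component area / bounding-box area, i.e. a convexity
  proxy) is an invented monotone ranking; detection evaluation only needs
  a ranking, not calibrated probabilities.
"""

from __future__ import annotations

import dataclasses
import json
import shlex
import subprocess
import tempfile
from abc import ABC, abstractmethod
from pathlib import Path

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon, box
from skimage import color, filters, measure

from ._geometry import clean_polygon, polygon_from_mask, rasterize_polygon

GRAPE_CLASS = "grape-bunch"


class BackendError(RuntimeError):
    """A segmentation backend is unavailable or failed to produce output.

    Distinct from an *empty* result: an empty mask or an empty instance
    list is a valid answer, this exception is not.
    """


@dataclasses.dataclass
class InstanceShape:
    """One detected or annotated grape bunch.

    polygon
        Simple polygon in image (or patch-local) pixel coordinates,
        x = column, y = row, origin top-left.
    confidence
        Detector score in [0, 1]; ground-truth instances use 1.0.
    class_label
        Single-class problem; defaults to ``"grape-bunch"``.
    source_patch
        Index of the patch that produced the detection, if any.
    """

    polygon: Polygon
    confidence: float = 1.0
    class_label: str = GRAPE_CLASS
    source_patch: int | None = None

    def __post_init__(self) -> None:
        poly = clean_polygon(self.polygon)
        if poly.is_empty or poly.area <= 0:
            raise ValueError("instance polygon must have positive area")
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda p: p.area)
        if len(poly.exterior.coords) < 4:  # closed ring: 3 vertices + repeat
            raise ValueError("instance polygon needs at least 3 vertices")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")
        self.polygon = poly

    def translated(self, dx: float, dy: float) -> "InstanceShape":
        from shapely import affinity

        return dataclasses.replace(
            self, polygon=affinity.translate(self.polygon, xoff=dx, yoff=dy)
        )

    def to_mask(self, height: int, width: int) -> np.ndarray:
        return rasterize_polygon(self.polygon, height, width)


def _as_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError(f"expected an RGB image, got shape {image.shape}")
    return image[..., :3]


class ForegroundBackend(ABC):
    """Stage-1 contract: image + free-text query -> boolean foreground mask."""

    @abstractmethod
    def refer_segment(self, image: np.ndarray, query: str) -> np.ndarray: ...


class InstanceBackend(ABC):
    """Stage-4 contract: image patch -> instances in patch-local coordinates."""

    @abstractmethod
    def detect_instances(self, patch: np.ndarray) -> list[InstanceShape]: ...


class LuminanceForeground(ForegroundBackend):
    """Reference stage-1 backend: Otsu threshold + dominant bright band.

    Pixels above the Otsu luminance threshold are labelled; holes are
    filled (dark grape bunches punch holes in a bright canopy); the
    largest connected component defines the foreground band's row
    interval, and only components whose rows overlap that interval and
    whose area exceeds ``min_component_fraction`` of the largest are
    retained. A second bright band elsewhere in the image (a background
    row) is therefore discarded.
    """

    def __init__(self, min_component_fraction: float = 0.05) -> None:
        self.min_component_fraction = min_component_fraction

    def refer_segment(self, image: np.ndarray, query: str) -> np.ndarray:
        image = _as_rgb(image)
        lum = color.rgb2gray(image)
        if np.ptp(lum) == 0:  # constant image: nothing to separate
            return np.zeros(lum.shape, dtype=bool)
        thresh = filters.threshold_otsu(lum)
        bright = lum > thresh
        if not bright.any():
            return bright
        bright = ndimage.binary_fill_holes(bright)
        labels = measure.label(bright, connectivity=2)
        props = measure.regionprops(labels)
        props.sort(key=lambda p: p.area, reverse=True)
        main = props[0]
        band_r0, band_r1 = main.bbox[0], main.bbox[2]
        keep = np.zeros_like(bright)
        for p in props:
            if p.area < self.min_component_fraction * main.area:
                continue
            r0, _, r1, _ = p.bbox
            if r1 > band_r0 and r0 < band_r1:  # row extent overlaps the band
                keep[labels == p.label] = True
        return keep


class HueBlobDetector(InstanceBackend):
    """Reference stage-4 backend: grape-hue blobs -> polygons.

    HSV hue window (default centred on blue-purple bunch color) with
    saturation/value floors, connected components, minimum-area filter,
    largest-contour extraction per component (Douglas-Peucker simplified),
    confidence = component area / bounding-box area.
    """

    def __init__(
        self,
        hue_range: tuple[float, float] = (0.6, 0.85),
        min_saturation: float = 0.25,
        min_value: float = 0.12,
        min_area: int = 30,
        simplify_tol: float = 1.0,
    ) -> None:
        self.hue_range = hue_range
        self.min_saturation = min_saturation
        self.min_value = min_value
        self.min_area = min_area
        self.simplify_tol = simplify_tol

    def detect_instances(self, patch: np.ndarray) -> list[InstanceShape]:
        patch = _as_rgb(patch)
        h, w = patch.shape[:2]
        if h < 8 or w < 8:
            raise ValueError(f"patch too small for detection: {w}x{h}")
        hsv = color.rgb2hsv(patch)
        lo, hi = self.hue_range
        hit = (
            (hsv[..., 0] >= lo)
            & (hsv[..., 0] <= hi)
            & (hsv[..., 1] >= self.min_saturation)
            & (hsv[..., 2] >= self.min_value)
        )
        hit = ndimage.binary_closing(hit, structure=np.ones((3, 3)))
        hit = ndimage.binary_fill_holes(hit)
        labels = measure.label(hit, connectivity=2)
        out: list[InstanceShape] = []
        for prop in measure.regionprops(labels):
            if prop.area < self.min_area:
                continue
            component = labels == prop.label
            poly = polygon_from_mask(component, simplify_tol=self.simplify_tol)
            if poly is None or poly.area <= 0:
                continue
            poly = poly.intersection(box(0.0, 0.0, float(w), float(h)))
            poly = clean_polygon(poly)
            if poly.is_empty or poly.area <= 0:
                continue
            r0, c0, r1, c1 = prop.bbox
            conf = float(prop.area) / float((r1 - r0) * (c1 - c0))
            out.append(
                InstanceShape(polygon=poly, confidence=min(conf, 1.0))
            )
        return out


class ForegroundCommandAdapter(ForegroundBackend):
    """Adapter running an external referring-segmentation model.

    ``command`` is a shell template with ``{input}``, ``{output}`` and
    ``{query}`` placeholders; the adapter writes the image as PNG, runs
    the command and reads back a 0/255 PNG mask.
    """

    def __init__(self, command: str) -> None:
        self.command = command

    def refer_segment(self, image: np.ndarray, query: str) -> np.ndarray:
        from PIL import Image

        with tempfile.TemporaryDirectory() as tmp:
            inp = Path(tmp) / "input.png"
            outp = Path(tmp) / "mask.png"
            Image.fromarray(_as_rgb(image)).save(inp)
            cmd = self.command.format(input=inp, output=outp, query=shlex.quote(query))
            try:
                subprocess.run(cmd, shell=True, check=True, capture_output=True)
            except (subprocess.CalledProcessError, OSError) as exc:
                raise BackendError(f"foreground adapter failed: {exc}") from exc
            if not outp.exists():
                raise BackendError("foreground adapter produced no mask file")
            mask = np.asarray(Image.open(outp).convert("L"))
        if mask.shape != image.shape[:2]:
            raise BackendError(
                f"adapter mask shape {mask.shape} != image shape {image.shape[:2]}"
            )
        return mask > 127


class InstanceCommandAdapter(InstanceBackend):
    """Adapter running an external instance-segmentation model.

    The command receives a PNG patch and must write JSON lines
    ``{"polygon": [[x, y], ...], "confidence": float, "class": str}``.
    """

    def __init__(self, command: str) -> None:
        self.command = command

    def detect_instances(self, patch: np.ndarray) -> list[InstanceShape]:
        from PIL import Image

        with tempfile.TemporaryDirectory() as tmp:
            inp = Path(tmp) / "patch.png"
            outp = Path(tmp) / "instances.jsonl"
            Image.fromarray(_as_rgb(patch)).save(inp)
            cmd = self.command.format(input=inp, output=outp)
            try:
                subprocess.run(cmd, shell=True, check=True, capture_output=True)
            except (subprocess.CalledProcessError, OSError) as exc:
                raise BackendError(f"instance adapter failed: {exc}") from exc
            if not outp.exists():
                raise BackendError("instance adapter produced no output file")
            text = outp.read_text()
        out = []
        for line in text.splitlines():
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                out.append(
                    InstanceShape(
                        polygon=Polygon(rec["polygon"]),
                        confidence=float(rec["confidence"]),
                        class_label=rec.get("class", GRAPE_CLASS),
                    )
                )
            except (KeyError, ValueError, json.JSONDecodeError) as exc:
                raise BackendError(f"malformed adapter output line: {line!r}") from exc
        return out
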