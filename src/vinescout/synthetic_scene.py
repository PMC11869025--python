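"""Seeded generator of vineyard-like scenes with exact ground truth.

The generator emulates the geometry a smartphone sees in a vertically
trellised vineyard row: a bright, in-focus foreground canopy band with
elliptical grape bunches, dimmer blurred background rows behind it, and
leaf occluders that hide a seeded fraction of bunches completely. Trunks
sit on the planting grid (2.5 m along the row, 3 m between rows, the
layout of the commercial vineyards this models) in a projected CRS.

Occlusion is modelled as whole-bunch hiding: a bunch is either fully
visible or fully covered by foliage. Field occlusion statistics are
count-based (a bunch entirely behind leaves simply cannot be counted from
the image), so the count unit, not partial pixel coverage, is what the
generator controls; partial occlusion is a rendering nicety it skips.

Every scene is driven by a single random stream derived from
``(seed, scene_index)``, so generating a plot of scenes is
order-independent and bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from shapely import affinity
from shapely.geometry import Point, Polygon

from ._geometry import rasterize_polygon
from .backends import InstanceShape

DEFAULT_CRS = "EPSG:25829"

# Render palette (RGB). The foreground band is markedly brighter than
# everything else so a luminance threshold can separate it; bunches carry
# a blue-purple hue disjoint from foliage greens.
_GROUND = np.array([72, 62, 52], dtype=float)
_SKY = np.array([150, 150, 148], dtype=float)
_BACK_ROW = np.array([52, 72, 44], dtype=float)
_CANOPY = np.array([132, 176, 92], dtype=float)
_CLUSTER = np.array([88, 52, 150], dtype=float)
_LEAF = np.array([118, 164, 84], dtype=float)


@dataclasses.dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic vineyard scene.

    ``foreground_band`` is the half-open row interval [y0, y1) occupied by
    the in-focus canopy; all bunches are placed inside it. ``trunk_origin``
    is the easting/northing of the plant's trunk in ``crs`` (defaults near
    the Rías Baixas vineyard block the package models).
    """

    width: int = 800
    height: int = 600
    n_clusters: int = 10
    cluster_radius_range: tuple[float, float] = (12.0, 24.0)
    occlusion_fraction: float = 0.2
    background_rows: int = 2
    foreground_band: tuple[int, int] = (330, 570)
    seed: int = 0
    trunk_origin: tuple[float, float] = (517204.2, 4645059.6)
    row_spacing: float = 3.0
    plant_spacing: float = 2.5
    crs: str = DEFAULT_CRS

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"non-positive scene dimensions {self.width}x{self.height}")
        if self.n_clusters < 0:
            raise ValueError("n_clusters must be >= 0")
        if not 0.0 <= self.occlusion_fraction <= 1.0:
            raise ValueError("occlusion_fraction must lie in [0, 1]")
        y0, y1 = self.foreground_band
        if not (0 <= y0 < y1 <= self.height):
            raise ValueError(f"foreground_band {self.foreground_band} outside image rows")
        rmin, rmax = self.cluster_radius_range
        if not (0 < rmin <= rmax):
            raise ValueError("cluster_radius_range must be positive and ordered")
        if 2 * rmax >= (y1 - y0):
            raise ValueError("cluster radius exceeds foreground band height")


@dataclasses.dataclass
class TrunkRecord:
    """One georeferenced vine trunk with optional attached bunch count."""

    plant_id: str
    easting: float
    northing: float
    crs: str = DEFAULT_CRS
    count: int | None = None
    esca_flag: bool = False
    replant_flag: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.easting) and np.isfinite(self.northing)):
            raise ValueError("trunk coordinates must be finite")
        if self.count is not None and self.count < 0:
            raise ValueError("count must be >= 0")


@dataclasses.dataclass
class SyntheticScene:
    image: np.ndarray
    foreground_mask: np.ndarray
    gt_instances: list[InstanceShape]
    visible_instances: list[InstanceShape]
    trunk: TrunkRecord
    occluded_count: int
    spec: SceneSpec


@dataclasses.dataclass(frozen=True)
class ClusterCountModel:
    """Distribution of bunches per plant.

    Field counts are overdispersed relative to Poisson (plant vigour,
    disease and pruning vary), so the default is a negative binomial with
    the mean observed at the study scale (449 bunches over 42 plants
    ≈ 10.7) and moderate dispersion. ``"poisson"`` and ``"fixed"`` are
    available alternatives.
    """

    name: str = "negbin"
    mean: float = 10.7
    dispersion: float = 4.0

    def draw(self, rng: np.random.Generator) -> int:
        if self.name == "fixed":
            return int(round(self.mean))
        if self.name == "poisson":
            return int(rng.poisson(self.mean))
        if self.name == "negbin":
            # NB as Gamma-Poisson mixture: n=k, p=k/(k+mean)
            k = self.dispersion
            p = k / (k + self.mean)
            return int(rng.negative_binomial(k, p))
        raise ValueError(f"unknown cluster-count model {self.name!r}")


def _scene_rng(seed: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def _ellipse(cx: float, cy: float, rx: float, ry: float, angle: float) -> Polygon:
    circ = Point(cx, cy).buffer(1.0, quad_segs=24)
    ell = affinity.scale(circ, rx, ry, origin=(cx, cy))
    return affinity.rotate(ell, angle, origin=(cx, cy))


def _place_clusters(spec: SceneSpec, rng: np.random.Generator) -> list[Polygon]:
    """Rejection-sample pairwise-disjoint bunch ellipses inside the band."""
    y0, y1 = spec.foreground_band
    rmin, rmax = spec.cluster_radius_range
    placed: list[Polygon] = []
    attempts = 0
    max_attempts = 400 * max(spec.n_clusters, 1)
    while len(placed) < spec.n_clusters and attempts < max_attempts:
        attempts += 1
        ry = rng.uniform(rmin, rmax)
        rx = ry * rng.uniform(0.55, 0.8)  # bunches hang taller than wide
        cx = rng.uniform(rx + 1, spec.width - rx - 1)
        cy = rng.uniform(y0 + ry + 1, y1 - ry - 1)
        angle = rng.uniform(-15, 15)
        cand = _ellipse(cx, cy, rx, ry, angle)
        if all(cand.distance(p) > 4.0 for p in placed):
            placed.append(cand)
    if len(placed) < spec.n_clusters:
        raise ValueError(
            f"could not place {spec.n_clusters} disjoint clusters in the band; "
            "reduce n_clusters or radius range"
        )
    return placed


def generate_scene(spec: SceneSpec, scene_index: int = 0) -> SyntheticScene:
    """Render one scene with exact ground truth.

    Background rows are dim and Gaussian-blurred; the foreground band is
    bright and sharp; bunches are blue-purple ellipses; a Bernoulli
    (``occlusion_fraction``) subset of bunches is covered entirely by a
    leaf-colored occluder and excluded from ``visible_instances``.
    """
    from scipy import ndimage

    spec.validate()
    rng = _scene_rng(spec.seed, scene_index)
    h, w = spec.height, spec.width
    y0, y1 = spec.foreground_band

    img = np.empty((h, w, 3), dtype=float)
    img[: h // 3] = _SKY * 0.55  # dim overcast sky strip
    img[h // 3 :] = _GROUND
    img += rng.normal(0, 6, size=img.shape)

    # background rows: dim green bands above the foreground band
    gap = max((y0 - h // 6) // (spec.background_rows + 1), 8)
    for i in range(spec.background_rows):
        top = h // 6 + i * gap
        bot = min(top + max(gap - 6, 6), y0 - 4)
        if bot <= top:
            continue
        band = _BACK_ROW + rng.normal(0, 10, size=(bot - top, w, 3))
        img[top:bot] = band
    img = ndimage.gaussian_filter(img, sigma=(2.5, 2.5, 0))  # defocused backdrop

    # sharp, bright foreground canopy
    canopy = _CANOPY + rng.normal(0, 14, size=(y1 - y0, w, 3))
    img[y0:y1] = canopy

    polys = _place_clusters(spec, rng)
    occluded = rng.random(len(polys)) < spec.occlusion_fraction if polys else np.array([], bool)

    for poly in polys:
        m = rasterize_polygon(poly, h, w)
        img[m] = _CLUSTER + rng.normal(0, 8, size=(int(m.sum()), 3))
    for poly, occ in zip(polys, occluded):
        if not occ:
            continue
        # leaf occluder: the bunch ellipse dilated so it is fully covered
        leaf = poly.buffer(4.0)
        m = rasterize_polygon(leaf, h, w)
        m[:y0] = False
        m[y1:] = False
        img[m] = _LEAF + rng.normal(0, 9, size=(int(m.sum()), 3))

    image = np.clip(img, 0, 255).astype(np.uint8)
    fg = np.zeros((h, w), dtype=bool)
    fg[y0:y1] = True

    gt = [InstanceShape(polygon=p, confidence=1.0) for p in polys]
    visible = [inst for inst, occ in zip(gt, occluded) if not occ]
    trunk = TrunkRecord(
        plant_id=f"plant_{scene_index:04d}",
        easting=spec.trunk_origin[0],
        northing=spec.trunk_origin[1],
        crs=spec.crs,
        count=len(gt),
    )
    return SyntheticScene(
        image=image,
        foreground_mask=fg,
        gt_instances=gt,
        visible_instances=visible,
        trunk=trunk,
        occluded_count=len(gt) - len(visible),
        spec=spec,
    )


def generate_plot(
    n_plants: int,
    spec_template: SceneSpec,
    clusters_per_plant: ClusterCountModel | None = None,
    plants_per_row: int = 14,
) -> tuple[list[SyntheticScene], list[TrunkRecord]]:
    """Generate one scene per plant with trunks on the planting grid.

    Plant ``i`` sits at column ``i % plants_per_row`` along its row
    (``plant_spacing`` apart) and row ``i // plants_per_row``
    (``row_spacing`` apart) from ``trunk_origin``. Per-plant bunch counts
    are drawn from ``clusters_per_plant`` on the plant's own stream.
    """
    if n_plants < 1:
        raise ValueError("n_plants must be >= 1")
    model = clusters_per_plant or ClusterCountModel()
    e0, n0 = spec_template.trunk_origin
    scenes: list[SyntheticScene] = []
    trunks: list[TrunkRecord] = []
    for i in range(n_plants):
        rng = _scene_rng(spec_template.seed, i)
        count = model.draw(rng)
        spec = dataclasses.replace(spec_template, n_clusters=count)
        scene = generate_scene(spec, scene_index=i)
        easting = e0 + (i % plants_per_row) * spec_template.plant_spacing
        northing = n0 + (i // plants_per_row) * spec_template.row_spacing
        trunk = dataclasses.replace(
            scene.trunk, easting=easting, northing=northing
        )
        scene.trunk = trunk
        scenes.append(scene)
        trunks.append(trunk)
    return scenes, trunks


# ---------------------------------------------------------------------------
# disk I/O: PNG image + JSON ground truth per scene, one CSV trunk table


def _instance_to_json(inst: InstanceShape) -> dict:
    return {
        "polygon": [[float(x), float(y)] for x, y in inst.polygon.exterior.coords[:-1]],
        "confidence": float(inst.confidence),
        "class": inst.class_label,
    }


def write_scene(scene: SyntheticScene, out_dir: Path | str, name: str) -> dict:
    """Write ``<name>.png`` and ``<name>.json`` ground truth; return the record."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    Image.fromarray(scene.image).save(out_dir / f"{name}.png")
    record = {
        "name": name,
        "width": scene.spec.width,
        "height": scene.spec.height,
        "seed": scene.spec.seed,
        "foreground_band": list(scene.spec.foreground_band),
        "gt_instances": [_instance_to_json(i) for i in scene.gt_instances],
        "visible_instances": [_instance_to_json(i) for i in scene.visible_instances],
        "occluded_count": scene.occluded_count,
        "trunk": {
            "plant_id": scene.trunk.plant_id,
            "easting": scene.trunk.easting,
            "northing": scene.trunk.northing,
            "crs": scene.trunk.crs,
        },
    }
    (out_dir / f"{name}.json").write_text(json.dumps(record, indent=1, sort_keys=True))
    return record


def write_trunk_table(scenes: list[SyntheticScene], path: Path | str) -> None:
    """CSV: plant_id, easting, northing, true_count, visible_count."""
    import pandas as pd

    rows = [
        {
            "plant_id": s.trunk.plant_id,
            "easting": s.trunk.easting,
            "northing": s.trunk.northing,
            "true_count": len(s.gt_instances),
            "visible_count": len(s.visible_instances),
        }
        for s in scenes
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
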