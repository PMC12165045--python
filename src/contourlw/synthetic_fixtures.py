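"""Synthetic top-view animal scenes with geometry-linked liveweights.

Each scene contains 1-4 non-overlapping animal-shaped blobs (an ellipse
body with a cosine head bump and a mild global bend) rendered onto a noisy
floor background. A simple perspective model scales each instance by its
position in the pen, so the same world-space animal appears with different
pixel sizes at different image locations. Liveweight is a deterministic
power law of the *world-space* (pre-projection) outline area plus
multiplicative Gaussian noise: a weight regressor working on image
contours must therefore exploit the positional cue to undo the projection,
which is exactly the property the contour pipeline is meant to exercise.

Defaults are tuned so the weights span roughly 30-115 kg, the growth range
of a fattening pig pen.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .contour_core import rasterize_contour, write_coco

__all__ = [
    "ShapeParams",
    "WeightModel",
    "CameraModel",
    "SceneRecord",
    "generate_shape",
    "polygon_area",
    "project_to_image",
    "assign_weight",
    "make_scene",
    "make_dataset",
    "contour_weight_instances",
]


@dataclass
class ShapeParams:
    """World-space animal outline parameters (world units ~ pixels at unit scale)."""

    a: float = 12.0  # body semi-major axis
    b: float = 6.0  # body semi-minor axis
    bump_amp: float = 0.25  # head bump, fraction of local radius
    bump_width: float = 0.5  # head bump angular width (radians)
    bend: float = 0.1  # banana bend, fraction of b per (x/a)^2
    orientation: float = 0.0  # radians
    position: tuple = (0.0, 0.0)  # pen position (pixels)
    roughness: float = 0.015  # smooth radial jitter amplitude

    def __post_init__(self):
        if not (self.a > self.b > 0):
            raise ValueError("need a > b > 0")
        if self.bump_amp < 0 or self.bump_width <= 0:
            raise ValueError("invalid head bump")


@dataclass
class WeightModel:
    """weight = k * (world area)^p * (1 + eps), eps ~ N(0, sigma^2)."""

    k: float = 0.28  # kg per world-area unit
    p: float = 1.0
    sigma: float = 0.02

    def __post_init__(self):
        if self.k <= 0 or self.p <= 0 or self.sigma < 0:
            raise ValueError("invalid weight model")


@dataclass
class CameraModel:
    """Affine position-dependent magnification: nearer pen rows image larger."""

    s_min: float = 0.85
    s_max: float = 1.15
    height: float = 96.0  # pen extent over which the scale varies

    def scale_at(self, position) -> float:
        frac = np.clip(position[1] / self.height, 0.0, 1.0)
        return self.s_min + (self.s_max - self.s_min) * frac


@dataclass
class SceneRecord:
    image: np.ndarray  # H x W x 3 uint8
    instances: list  # dicts: polygon (N,2) px, weight_kg, instance_id, animal_id, world_area
    camera: CameraModel
    scene_id: int = 0


def generate_shape(params: ShapeParams, rng=None, n_vertices: int = 256) -> np.ndarray:
    """World-space closed outline (n_vertices, 2), centred on its centroid.

    Ellipse base, cosine-tapered head bump at theta = 0, quadratic bend,
    optional smooth radial roughness drawn from `rng`, then rotation by
    `orientation` about the centroid.
    """
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    scale = 1.0 + params.bump_amp * np.exp(
        -0.5 * (np.angle(np.exp(1j * theta)) / params.bump_width) ** 2
    )
    if rng is not None and params.roughness > 0:
        # low-order Fourier jitter keeps the outline smooth and simple
        amp = params.roughness
        coeffs = rng.normal(0.0, amp, 4)
        phases = rng.uniform(0, 2 * np.pi, 4)
        for m, (c, ph) in enumerate(zip(coeffs, phases), start=2):
            scale = scale + c * np.cos(m * theta + ph)
    x = params.a * np.cos(theta) * scale
    y = params.b * np.sin(theta) * scale
    y = y + params.bend * params.b * (x / params.a) ** 2
    pts = np.stack([x, y], axis=1)
    pts -= pts.mean(axis=0)
    c, s = np.cos(params.orientation), np.sin(params.orientation)
    return pts @ np.array([[c, s], [-s, c]])


def polygon_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2)


def project_to_image(polygon: np.ndarray, position, camera: CameraModel) -> np.ndarray:
    """Scale a world outline by the camera magnification at `position` and
    translate it there (pixel coordinates)."""
    s = camera.scale_at(position)
    return polygon * s + np.asarray(position, dtype=float)


def assign_weight(params: ShapeParams, model: WeightModel, rng) -> float:
    """Liveweight from world geometry; independent of image position."""
    area = polygon_area(generate_shape(params, rng=None))
    eps = rng.normal(0.0, model.sigma) if model.sigma > 0 else 0.0
    return model.k * area**model.p * (1.0 + eps)


def _render(polys, animal_ids, height, width, rng) -> np.ndarray:
    img = rng.normal(45.0, 6.0, (height, width))
    base = np.clip(img, 0, 255)
    out = np.stack([base] * 3, axis=2)
    for poly, aid in zip(polys, animal_ids):
        mask = rasterize_contour(poly, height, width).astype(bool)
        level = 185.0 + 20.0 * np.sin(aid * 2.39996)  # stable per-animal shade
        body = rng.normal(level, 8.0, (height, width))
        tint = np.array([1.0, 0.97, 0.92])
        for ch in range(3):
            out[:, :, ch][mask] = np.clip(body[mask] * tint[ch], 0, 255)
    return out.astype(np.uint8)


def make_scene(
    scene_id: int,
    animals: list,
    weight_model: WeightModel,
    camera: CameraModel,
    rng,
    image_size=(96, 96),
    max_instances: int = 3,
) -> SceneRecord:
    """One rendered scene with non-overlapping projected instances."""
    width, height = image_size
    n_inst = int(rng.integers(1, max_instances + 1))
    chosen = rng.choice(len(animals), size=min(n_inst, len(animals)), replace=False)
    polys, metas, discs = [], [], []
    for aid in chosen:
        base = animals[aid]
        pose = replace(
            base,
            orientation=rng.uniform(0, 2 * np.pi),
            bend=base.bend * rng.uniform(0.5, 1.5),
        )
        world = generate_shape(pose, rng=rng)
        weight = assign_weight(pose, weight_model, rng)
        radius = float(np.linalg.norm(world, axis=1).max()) * camera.s_max
        placed = None
        for _ in range(300):
            pos = rng.uniform([radius + 2, radius + 2], [width - radius - 2, height - radius - 2])
            if all(np.hypot(*(pos - q)) > radius + r + 3 for q, r in discs):
                placed = pos
                break
        if placed is None:
            continue
        proj = project_to_image(world, placed, camera)
        discs.append((placed, radius))
        polys.append(proj)
        metas.append(
            {
                "animal_id": int(aid),
                "weight_kg": float(weight),
                "world_area": polygon_area(world),
                "position": tuple(placed),
            }
        )
    image = _render(polys, [m["animal_id"] for m in metas], height, width, rng)
    instances = [
        {"instance_id": i, "polygon": poly, **meta}
        for i, (poly, meta) in enumerate(zip(polys, metas))
    ]
    return SceneRecord(image=image, instances=instances, camera=camera, scene_id=scene_id)


def _default_animals(rng, n_animals: int = 13):
    animals = []
    for _ in range(n_animals):
        a = rng.uniform(9.0, 16.0)
        animals.append(
            ShapeParams(
                a=a,
                b=a * rng.uniform(0.42, 0.58),
                bump_amp=rng.uniform(0.15, 0.3),
                bump_width=rng.uniform(0.4, 0.6),
                bend=rng.uniform(0.05, 0.18),
            )
        )
    return animals


def make_dataset(
    n_scenes: int = 100,
    max_instances: int = 3,
    seed: int = 0,
    split_fractions=(0.6, 0.2, 0.2),
    image_size=(96, 96),
    weight_model: WeightModel | None = None,
    out_dir=None,
) -> dict:
    """Reproducible train/val/test scene sets (+ optional COCO JSON & CSV).

    Scenes are stratified across splits by their mean instance weight so
    every split covers the full growth range. With `out_dir` set, PNG
    images, per-split COCO polygon files and a weight CSV are written.
    """
    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    wm = weight_model or WeightModel()
    master = np.random.default_rng(seed)
    animals = _default_animals(master)
    camera = CameraModel(height=float(image_size[1]))
    scenes = []
    for sid in range(n_scenes):
        rng = np.random.default_rng([seed, sid])  # per-scene fan-out
        scenes.append(
            make_scene(sid, animals, wm, camera, rng, image_size, max_instances)
        )
    # stratified split on mean scene weight
    keys = np.array(
        [np.mean([i["weight_kg"] for i in s.instances]) if s.instances else 0.0 for s in scenes]
    )
    order = np.argsort(keys, kind="stable")
    n_train = int(round(split_fractions[0] * n_scenes))
    n_val = int(round(split_fractions[1] * n_scenes))
    assign = np.empty(n_scenes, dtype=object)
    slots = ["train"] * n_train + ["val"] * n_val + ["test"] * (n_scenes - n_train - n_val)
    # deal the weight-sorted scenes round-robin into the split quota
    quota = {"train": n_train, "val": n_val, "test": n_scenes - n_train - n_val}
    counts = {k: 0 for k in quota}
    cycle = ["train", "val", "test"]
    ci = 0
    for idx in order:
        for _ in range(3):
            split = cycle[ci % 3]
            ci += 1
            if counts[split] < quota[split]:
                assign[idx] = split
                counts[split] += 1
                break
        else:
            assign[idx] = max(quota, key=lambda k: quota[k] - counts[k])
            counts[assign[idx]] += 1
    splits = {k: [s for s, a in zip(scenes, assign) if a == k] for k in cycle}
    if out_dir is not None:
        _export(splits, Path(out_dir), image_size)
    return splits


def _export(splits: dict, out_dir: Path, image_size) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    img_dir = out_dir / "images"
    img_dir.mkdir(exist_ok=True)
    rows = []
    for split, scenes in splits.items():
        images, anns = [], []
        for s in scenes:
            fname = f"scene_{s.scene_id:05d}.png"
            Image.fromarray(s.image).save(img_dir / fname)
            images.append(
                {
                    "id": s.scene_id,
                    "width": int(image_size[0]),
                    "height": int(image_size[1]),
                    "file_name": fname,
                }
            )
            for inst in s.instances:
                anns.append(
                    {
                        "id": s.scene_id * 100 + inst["instance_id"],
                        "image_id": s.scene_id,
                        "segmentation": inst["polygon"].flatten().tolist(),
                    }
                )
                rows.append(
                    (s.scene_id, inst["instance_id"], inst["animal_id"],
                     round(inst["weight_kg"], 3), split)
                )
        write_coco(out_dir / f"instances_{split}.json", images, anns)
    with open(out_dir / "weights.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["image_id", "instance_id", "animal_id", "weight_kg", "split"])
        w.writerows(rows)


def contour_weight_instances(n_instances: int, seed: int = 0, image_size=(96, 96), sigma: float = 0.02):
    """Flat list of (pixel polygon, image dims, weight) pairs for training a
    weight regressor on ground-truth outlines."""
    wm = WeightModel(sigma=sigma)
    out = []
    scenes_needed = 0
    splits = None
    # generate scenes until enough instances accumulated
    per_batch = max(8, n_instances // 2)
    batch = 0
    while len(out) < n_instances:
        splits = make_dataset(
            n_scenes=per_batch,
            seed=seed + 7919 * batch,
            split_fractions=(1.0, 0.0, 0.0),
            image_size=image_size,
            weight_model=wm,
        )
        for s in splits["train"]:
            for inst in s.instances:
                out.append((inst["polygon"], image_size, inst["weight_kg"]))
                if len(out) == n_instances:
                    return out
        batch += 1
    return out
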