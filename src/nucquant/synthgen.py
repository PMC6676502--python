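"""Ground-truth synthetic two-channel images of stained nuclei.

Real confocal images of motor-neuron nuclei are not distributed with this
package, so every pipeline stage is exercised on synthetic images: hard
disks of known radius and intensity (nuclei) on a uniform background, with
optional additive Gaussian noise.  The marker channel (nuclear stain) goes
to the red samples of an RGB TIFF and the query channel (measured signal)
to the green samples, mirroring the tool's RGB input contract.

Defaults emulate a ventral-ganglion field of view at the scale where a
nucleus spans 10-16 px: 192x192 images, 12 non-overlapping nuclei of radius
5-8 px, marker level 200 on background 20, query means drawn per nucleus,
noise SD 5.  Generation is fully deterministic for a fixed seed.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence, Union

import numpy as np
from skimage.draw import disk as draw_disk

from .image_io import RGBStack, write_rgb_stack

_MAX_PLACEMENT_ATTEMPTS = 10_000


@dataclass
class SynthSpec:
    """Parameters of one synthetic two-channel image.

    ``query_means`` is either an explicit per-nucleus list of mean levels or
    a ``(mu, sd)`` tuple from which per-nucleus means are drawn (truncated
    to the valid intensity range).  ``min_center_spacing=None`` defaults to
    non-overlapping placement (2*max radius + 2); pass ``allow_touching=True``
    to generate merged blobs that exercise the watershed.
    """

    image_size: tuple[int, int] = (192, 192)
    n_nuclei: int = 12
    radius_range: tuple[int, int] = (5, 8)
    marker_intensity: int = 200
    query_means: Union[Sequence[float], tuple[float, float]] = (120.0, 15.0)
    query_means_are_list: bool = False
    background_level: int = 20
    noise_sd: float = 5.0
    min_center_spacing: float | None = None
    allow_touching: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_level >= self.marker_intensity:
            raise ValueError("background_level must be below marker_intensity")
        if self.query_means_are_list and len(self.query_means) != self.n_nuclei:
            raise ValueError("query_means list length must equal n_nuclei")

    def spacing(self) -> float:
        if self.min_center_spacing is not None:
            return self.min_center_spacing
        if self.allow_touching:
            return float(self.radius_range[1])  # guaranteed overlaps possible
        return 2.0 * self.radius_range[1] + 2.0

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "SynthSpec":
        d = json.loads(text)
        d["image_size"] = tuple(d["image_size"])
        d["radius_range"] = tuple(d["radius_range"])
        if not d.get("query_means_are_list"):
            d["query_means"] = tuple(d["query_means"])
        return cls(**d)


@dataclass
class GroundTruth:
    """What was actually rendered: one entry per nucleus plus the label image."""

    centers: list[tuple[int, int]]  # (row, col)
    radii: list[int]
    query_means: list[float]  # nominal per-nucleus query level (pre-noise)
    background_level: int
    label_image: np.ndarray
    n_clipped: int = 0

    @property
    def n_nuclei(self) -> int:
        return len(self.centers)


def _place_centers(spec: SynthSpec, rng: np.random.Generator) -> tuple[list, list]:
    h, w = spec.image_size
    rmin, rmax = spec.radius_range
    spacing = spec.spacing()
    centers: list[tuple[int, int]] = []
    radii: list[int] = []
    attempts = 0
    while len(centers) < spec.n_nuclei:
        attempts += 1
        if attempts > _MAX_PLACEMENT_ATTEMPTS:
            raise RuntimeError(
                f"could not place {spec.n_nuclei} nuclei at spacing "
                f"{spacing:.1f} in a {h}x{w} image; use fewer or smaller nuclei"
            )
        r = int(rng.integers(rmin, rmax + 1))
        row = int(rng.integers(r, h - r))
        col = int(rng.integers(r, w - r))
        ok = all(
            (row - cr) ** 2 + (col - cc) ** 2 >= spacing**2 for cr, cc in centers
        )
        if ok:
            centers.append((row, col))
            radii.append(r)
    return centers, radii


def generate_image(spec: SynthSpec) -> tuple[RGBStack, GroundTruth]:
    """Render one synthetic marker/query image pair as a 1-slice RGB stack.

    The marker channel holds disks at ``marker_intensity`` on
    ``background_level``; the query channel holds the same disks at their
    per-nucleus query means on the same background.  Gaussian noise of SD
    ``noise_sd`` is added (when non-zero), values are clipped to [0, 255]
    (clip count recorded in the ground truth) and quantized to uint8.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    centers, radii = _place_centers(spec, rng)

    if spec.query_means_are_list:
        qmeans = [float(v) for v in spec.query_means]
    else:
        mu, sd = spec.query_means
        qmeans = []
        for _ in range(spec.n_nuclei):
            v = float(rng.normal(mu, sd))
            qmeans.append(float(np.clip(v, spec.background_level + 1, 255)))

    marker = np.full((h, w), float(spec.background_level))
    query = np.full((h, w), float(spec.background_level))
    labels = np.zeros((h, w), dtype=np.int32)
    for i, ((row, col), r) in enumerate(zip(centers, radii), start=1):
        rr, cc = draw_disk((row, col), r, shape=(h, w))
        marker[rr, cc] = spec.marker_intensity
        query[rr, cc] = qmeans[i - 1]
        labels[rr, cc] = i

    n_clipped = 0
    planes = []
    for plane in (marker, query):
        if spec.noise_sd > 0:
            plane = plane + rng.normal(0.0, spec.noise_sd, size=plane.shape)
        n_clipped += int(np.sum((plane < 0) | (plane > 255)))
        planes.append(np.round(np.clip(plane, 0, 255)).astype(np.uint8))

    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    rgb[..., 0] = planes[0]  # marker -> red
    rgb[..., 1] = planes[1]  # query -> green
    stack = RGBStack(planes=rgb[np.newaxis])
    truth = GroundTruth(
        centers=centers,
        radii=radii,
        query_means=qmeans,
        background_level=spec.background_level,
        label_image=labels,
        n_clipped=n_clipped,
    )
    return stack, truth


def derive_seed(base_seed: int, group_index: int, image_index: int) -> int:
    """Deterministic per-image seed below 2**31."""
    return (base_seed * 100_003 + group_index * 10_007 + image_index) % (2**31)


def generate_experiment(
    control_spec: SynthSpec,
    experimental_spec: SynthSpec,
    n_images_per_group: int,
    out_dir: Union[str, os.PathLike],
    group_names: tuple[str, str] = ("control", "experimental"),
) -> str:
    """Write a two-group image set plus a manifest CSV; return the manifest path.

    Emulates a two-genotype comparison: ``n_images_per_group`` TIFFs per
    group, with per-image seeds derived from each spec's base seed and the
    image index.  The manifest lists file, group, seed, and per-image truth
    summary (n nuclei, mean nominal query level, background).
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    manifest_path = os.path.join(out_dir, "manifest.csv")
    with open(manifest_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["file", "group", "seed", "n_nuclei", "true_query_mean", "background_level"]
        )
        for gi, (name, spec) in enumerate(
            zip(group_names, (control_spec, experimental_spec))
        ):
            for i in range(n_images_per_group):
                img_spec = replace(spec, seed=derive_seed(spec.seed, gi, i))
                stack, truth = generate_image(img_spec)
                fname = f"{name}_{i:02d}.tif"
                write_rgb_stack(os.path.join(out_dir, fname), stack)
                writer.writerow(
                    [
                        fname,
                        name,
                        img_spec.seed,
                        truth.n_nuclei,
                        f"{np.mean(truth.query_means):.6f}",
                        truth.background_level,
                    ]
                )
    return manifest_path
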