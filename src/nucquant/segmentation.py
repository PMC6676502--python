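"""Nuclei segmentation on the marker channel.

The marker channel (e.g. a pan-neuronal nuclear stain such as Elav) is used
solely to locate nuclei: the analyst delimits the tissue of interest with a
polygonal selection, everything outside is cleared, a threshold (automatic or
manual) binarizes the in-selection pixels, optional binary operations
(dilate, then distance-transform watershed) tidy the mask, and a particle
analysis returns the connected components that pass area and circularity
filters.  These particles become the ROIs on which the query channel is
measured.

Conventions follow the common particle-analysis practice of interactive image
analysis platforms: 8-connected foreground, circularity 4*pi*A/P^2 clamped at
1.0, and a dark-background threshold (foreground = bright pixels).
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .image_io import ChannelImage

_STRUCT8 = np.ones((3, 3), dtype=bool)


# --------------------------------------------------------------------------
# selection region
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionRegion:
    """A simple polygon delimiting the analyzed tissue, or the whole image.

    Vertices are ``(x, y)`` pixel coordinates (x = column, y = row).
    Membership uses the even-odd rule; pixels whose center lies exactly on a
    polygon edge count as inside.
    """

    vertices: tuple[tuple[float, float], ...] | None = None

    @classmethod
    def whole_image(cls) -> "SelectionRegion":
        return cls(vertices=None)

    @classmethod
    def polygon(cls, vertices: Iterable[Sequence[float]]) -> "SelectionRegion":
        verts = tuple((float(x), float(y)) for x, y in vertices)
        if len(verts) < 3:
            raise ValueError("a polygonal selection needs at least 3 vertices")
        return cls(vertices=verts)

    @property
    def is_whole_image(self) -> bool:
        return self.vertices is None

    def signed_area(self) -> float:
        if self.vertices is None:
            return float("inf")
        xs = np.array([v[0] for v in self.vertices])
        ys = np.array([v[1] for v in self.vertices])
        return 0.5 * float(np.sum(xs * np.roll(ys, -1) - np.roll(xs, -1) * ys))

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterize the selection as a boolean mask of the given (h, w)."""
        h, w = shape
        if self.vertices is None:
            return np.ones(shape, dtype=bool)
        xs = np.array([v[0] for v in self.vertices], dtype=np.float64)
        ys = np.array([v[1] for v in self.vertices], dtype=np.float64)
        if xs.min() < 0 or ys.min() < 0 or xs.max() > w - 1 or ys.max() > h - 1:
            warnings.warn(
                "selection vertices outside image bounds were clipped", stacklevel=2
            )
            xs = np.clip(xs, 0, w - 1)
            ys = np.clip(ys, 0, h - 1)
        area = 0.5 * abs(np.sum(xs * np.roll(ys, -1) - np.roll(xs, -1) * ys))
        if area == 0:
            raise ValueError("degenerate selection polygon (zero area)")
        return _polygon_mask(xs, ys, shape)


def _polygon_mask(xs: np.ndarray, ys: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Even-odd rasterization with boundary pixel centers counted inside.

    Vectorized crossing-number test over all pixel centers, plus an exact
    on-segment test so that centers lying on an edge are always inside
    regardless of crossing parity.
    """
    h, w = shape
    py, px = np.mgrid[0:h, 0:w]
    px = px.astype(np.float64)
    py = py.astype(np.float64)
    inside = np.zeros(shape, dtype=bool)
    on_edge = np.zeros(shape, dtype=bool)
    n = len(xs)
    for i in range(n):
        x1, y1 = xs[i], ys[i]
        x2, y2 = xs[(i + 1) % n], ys[(i + 1) % n]
        # crossing-number: does a leftward horizontal ray from the pixel
        # center cross edge (x1,y1)-(x2,y2)?
        cond = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        crosses = cond & (px < x_int)
        inside ^= crosses
        # exact on-segment test
        dx, dy = x2 - x1, y2 - y1
        cross = (px - x1) * dy - (py - y1) * dx
        dot = (px - x1) * dx + (py - y1) * dy
        seg_len2 = dx * dx + dy * dy
        if seg_len2 > 0:
            on_edge |= (cross == 0) & (dot >= 0) & (dot <= seg_len2)
        else:
            on_edge |= (px == x1) & (py == y1)
    return inside | on_edge


def clear_outside_selection(
    channel: ChannelImage, selection: SelectionRegion
) -> ChannelImage:
    """Return a copy of the channel with pixels outside the selection set to 0."""
    mask = selection.to_mask(channel.shape)
    values = np.where(mask, channel.values, 0).astype(channel.values.dtype)
    return ChannelImage(values, channel.channel_name, channel.source_path)


# --------------------------------------------------------------------------
# thresholding
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdSpec:
    """Inclusive intensity window [min_level, max_level] selecting foreground.

    ``mode`` records whether the levels were supplied by the user ("manual")
    or computed ("auto"); ``method`` names the auto algorithm used, if any.
    """

    min_level: int
    max_level: int = 255
    mode: str = "manual"
    method: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.min_level <= self.max_level <= 255):
            raise ValueError(
                f"threshold levels must satisfy 0 <= min <= max <= 255, "
                f"got ({self.min_level}, {self.max_level})"
            )


def _isodata_level(hist: np.ndarray) -> int:
    """Iterative intermeans (IsoData variant used as the 'Default' method).

    Returns the level L such that foreground is L+1..255: repeatedly place
    the cut at the mean of the below-cut mean and the above-cut mean until it
    stabilizes.
    """
    max_value = len(hist) - 1
    lo = 0
    while hist[lo] == 0 and lo < max_value:
        lo += 1
    hi = max_value
    while hist[hi] == 0 and hi > 0:
        hi -= 1
    if lo >= hi:
        return len(hist) // 2
    moving = lo
    while True:
        below = np.arange(lo, moving + 1)
        above = np.arange(moving + 1, hi + 1)
        sum2 = hist[below].sum()
        sum4 = hist[above].sum()
        result = ((below * hist[below]).sum() / sum2 + (above * hist[above]).sum() / sum4) / 2.0
        moving += 1
        if not (moving + 1 <= result and moving < hi - 1):
            break
    return int(round(result))


def _otsu_level(hist: np.ndarray) -> int:
    """Otsu's cut maximizing between-class variance, vectorized.

    Returns the smallest cut t (foreground = t..255) achieving the maximum,
    expressed as the level t-1 so that foreground is level+1..255, matching
    the IsoData convention.
    """
    hist = hist.astype(np.float64)
    total = hist.sum()
    omega0 = np.cumsum(hist)[:-1]  # class 0 = bins 0..t-1 for cut t=1..255
    omega1 = total - omega0
    mu_cum = np.cumsum(np.arange(len(hist)) * hist)[:-1]
    mu_total = (np.arange(len(hist)) * hist).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / omega0
        mu1 = (mu_total - mu_cum) / omega1
        var_between = omega0 * omega1 * (mu0 - mu1) ** 2
    var_between = np.nan_to_num(var_between, nan=-1.0)
    cut = int(np.argmax(var_between)) + 1
    return cut - 1


_AUTO_METHODS = {"default": _isodata_level, "isodata": _isodata_level, "otsu": _otsu_level}


def auto_threshold(
    channel: ChannelImage,
    selection: SelectionRegion | None = None,
    method: str = "default",
) -> ThresholdSpec:
    """Compute a threshold from the histogram of in-selection pixels only.

    Returns a manual-equivalent spec with ``min_level = level + 1`` (bright
    foreground on dark background) and ``max_level = 255``; the method name
    is recorded in the spec.  A constant in-selection intensity is an error
    advising manual mode.
    """
    if method not in _AUTO_METHODS:
        raise ValueError(f"unknown auto-threshold method {method!r}")
    selection = selection or SelectionRegion.whole_image()
    sel = selection.to_mask(channel.shape)
    pixels = channel.values[sel]
    if pixels.size == 0 or np.unique(pixels).size < 2:
        raise ValueError(
            "in-selection intensity is constant; automatic thresholding is "
            "undefined - supply a manual threshold instead"
        )
    hist = np.bincount(pixels.ravel(), minlength=256)
    level = _AUTO_METHODS[method](hist)
    return ThresholdSpec(
        min_level=min(level + 1, 255), max_level=255, mode="auto", method=method
    )


@dataclass
class BinaryMask:
    """A boolean mask with the same shape as its source channel."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("BinaryMask values must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def count(self) -> int:
        return int(self.values.sum())


def apply_threshold(
    channel: ChannelImage,
    spec: ThresholdSpec,
    selection: SelectionRegion | None = None,
) -> BinaryMask:
    """Mask true exactly where min <= intensity <= max and inside the selection."""
    selection = selection or SelectionRegion.whole_image()
    sel = selection.to_mask(channel.shape)
    vals = channel.values
    mask = (vals >= spec.min_level) & (vals <= spec.max_level) & sel
    return BinaryMask(mask)


# --------------------------------------------------------------------------
# binary operations
# --------------------------------------------------------------------------

def binary_dilate(mask: BinaryMask, iterations: int = 1) -> BinaryMask:
    """Morphological dilation with a 3x3 all-true structuring element.

    Applied ``iterations`` times; iterations=0 is the identity.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return BinaryMask(mask.values.copy())
    out = ndi.binary_dilation(mask.values, structure=_STRUCT8, iterations=iterations)
    return BinaryMask(out)


def binary_watershed(mask: BinaryMask) -> BinaryMask:
    """Split touching convex blobs with a distance-transform watershed.

    Markers are the regional maxima of the Euclidean distance transform; the
    watershed runs on the negated distance map and inserts one-pixel-wide
    background ridges between basins.  Foreground area never increases, and a
    blob with a single distance maximum is returned unchanged.
    """
    values = mask.values
    if not values.any():
        return BinaryMask(values.copy())
    dist = ndi.distance_transform_edt(values)
    lbl, _ = ndi.label(values, structure=_STRUCT8)
    coords = peak_local_max(
        dist, footprint=np.ones((3, 3)), labels=lbl, exclude_border=False
    )
    markers = np.zeros(values.shape, dtype=np.int32)
    markers[tuple(coords.T)] = 1
    markers, _ = ndi.label(markers, structure=_STRUCT8)
    ws = watershed(-dist, markers, mask=values, watershed_line=True, connectivity=2)
    return BinaryMask(values & (ws > 0))


# --------------------------------------------------------------------------
# particle analysis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ParticleFilter:
    """Size and shape filters applied to candidate particles.

    Areas are in pixels; circularity = 4*pi*area/perimeter^2, dimensionless
    in [0, 1].  ``apply_dilate`` and ``apply_watershed`` request the binary
    operations to be run (in that order) between thresholding and analysis.
    ``exclude_edge_particles`` drops particles touching the image border
    (off by default).
    """

    min_area: float = 0.0
    max_area: float = float("inf")
    min_circ: float = 0.0
    max_circ: float = 1.0
    apply_watershed: bool = False
    apply_dilate: bool = False
    dilate_iterations: int = 1
    exclude_edge_particles: bool = False

    def __post_init__(self) -> None:
        if self.min_area > self.max_area:
            raise ValueError("min_area must be <= max_area")
        if not (0 <= self.min_circ <= self.max_circ <= 1):
            raise ValueError("circularity bounds must satisfy 0 <= min <= max <= 1")
        if self.dilate_iterations < 0:
            raise ValueError("dilate_iterations must be >= 0")


@dataclass
class Particle:
    """One connected component (candidate nucleus) that passed the filters.

    ``coords`` is an (n, 2) array of (row, col) pixel indices; ``centroid``
    and ``bbox`` use (x, y) = (col, row) ordering.
    """

    label: int
    coords: np.ndarray
    area: int
    perimeter: float
    circularity: float
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]  # (x0, y0, x1, y1), exclusive upper bounds

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.coords[:, 0], self.coords[:, 1]] = True
        return m


def _circularity(area: float, perimeter: float) -> float:
    if perimeter <= 0:
        return 1.0  # degenerate (single pixel); clamp convention
    return min(1.0, 4.0 * np.pi * area / perimeter**2)


def analyze_particles(mask: BinaryMask, pfilter: ParticleFilter) -> list[Particle]:
    """Label 8-connected components and keep those passing the filters.

    Labels are assigned in raster-scan order of each component's first pixel.
    Any requested dilate/watershed must already have been applied to ``mask``.
    """
    values = mask.values
    lbl, n = ndi.label(values, structure=_STRUCT8)
    if n == 0:
        return []
    # relabel deterministically by raster order of first pixel
    first_index = ndi.minimum(
        np.arange(values.size).reshape(values.shape), lbl, index=np.arange(1, n + 1)
    )
    order = np.argsort(first_index, kind="stable")
    h, w = values.shape
    props = {p.label: p for p in regionprops(lbl)}
    particles: list[Particle] = []
    out_label = 0
    for old in order + 1:
        rp = props[int(old)]
        area = int(rp.area)
        # Crofton estimate tracks the true boundary length of digitized
        # disks closely, so disk circularity approaches 1 with radius.
        perim = float(rp.perimeter_crofton)
        circ = _circularity(area, perim)
        if not (pfilter.min_area <= area <= pfilter.max_area):
            continue
        if not (pfilter.min_circ <= circ <= pfilter.max_circ):
            continue
        r0, c0, r1, c1 = rp.bbox
        if pfilter.exclude_edge_particles and (
            r0 == 0 or c0 == 0 or r1 == h or c1 == w
        ):
            continue
        out_label += 1
        coords = rp.coords.copy()
        cy, cx = rp.centroid
        particles.append(
            Particle(
                label=out_label,
                coords=coords,
                area=area,
                perimeter=perim,
                circularity=circ,
                centroid=(float(cx), float(cy)),
                bbox=(c0, r0, c1, r1),
            )
        )
    return particles


def edit_particles(
    particles: Sequence[Particle],
    include_ids: Sequence[int] = (),
    exclude_ids: Sequence[int] = (),
) -> list[Particle]:
    """Headless surrogate for interactive ROI correction.

    Removes excluded labels; if ``include_ids`` is non-empty, keeps only
    those.  A label appearing in both lists, or an unknown label, is refused.
    """
    known = {p.label for p in particles}
    include = set(include_ids)
    exclude = set(exclude_ids)
    for label in sorted((include | exclude) - known):
        raise ValueError(f"unknown particle id {label}")
    conflict = include & exclude
    if conflict:
        raise ValueError(
            f"particle id(s) {sorted(conflict)} listed as both include and exclude"
        )
    kept = [p for p in particles if p.label not in exclude]
    if include:
        kept = [p for p in kept if p.label in include]
    return kept


# --------------------------------------------------------------------------
# ImageJ .roi polygon files (read-only)
# --------------------------------------------------------------------------

def read_imagej_roi(path: str) -> SelectionRegion:
    """Read a polygon selection from the standard binary ``.roi`` format.

    Supports polygon-type ROIs only (the selection-area use case); other ROI
    types raise :class:`ValueError`.
    """
    with open(path, "rb") as fh:
        data = fh.read()
    if data[:4] != b"Iout":
        raise ValueError(f"{path}: not an ImageJ .roi file")
    roi_type = data[6]
    if roi_type != 0:  # 0 = polygon
        raise ValueError(f"{path}: unsupported ROI type {roi_type}; need polygon")
    top, left = struct.unpack(">hh", data[8:12])
    n = struct.unpack(">h", data[16:18])[0]
    xs = struct.unpack(f">{n}h", data[64 : 64 + 2 * n])
    ys = struct.unpack(f">{n}h", data[64 + 2 * n : 64 + 4 * n])
    vertices = [(left + x, top + y) for x, y in zip(xs, ys)]
    return SelectionRegion.polygon(vertices)
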