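"""Reading multi-channel TIFF stacks, channel splitting, and CSV export.

Input images are baseline TIFFs carrying interleaved RGB samples, single- or
multi-slice.  All pixel data are handled under an 8-bit contract: 16-bit
inputs are rescaled to [0, 255] on load.  Pixel coordinates are row-major,
0-based, origin at the top-left corner.
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence, Union

import numpy as np
import tifffile

if TYPE_CHECKING:  # pragma: no cover
    from .measurement import ImageSummary, QuantResult

log = logging.getLogger(__name__)

CHANNEL_NAMES = ("red", "green", "blue")

#: CSV header shared by every per-image results file.
CSV_HEADER = (
    "image",
    "roi_id",
    "area_px",
    "mean_raw",
    "mean_bg",
    "mean_corrected",
    "centroid_x",
    "centroid_y",
)


class FormatError(ValueError):
    """Raised when a file exists but does not satisfy the RGB TIFF contract."""


@dataclass
class RGBStack:
    """An 8-bit RGB TIFF stack in memory.

    ``planes`` has shape ``(n_slices, height, width, 3)`` with dtype uint8;
    every slice shares the same height and width by construction.
    """

    planes: np.ndarray
    source_path: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.planes)
        if arr.ndim == 3:  # single slice (h, w, 3)
            arr = arr[np.newaxis]
        if arr.ndim != 4 or arr.shape[-1] != 3:
            raise FormatError(
                f"expected (n_slices, h, w, 3) RGB data, got shape {arr.shape}"
            )
        if arr.dtype != np.uint8:
            if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
                arr = arr.astype(np.uint8)
            else:
                raise FormatError("RGBStack pixels must be 8-bit integers in [0, 255]")
        self.planes = arr

    @property
    def n_slices(self) -> int:
        return self.planes.shape[0]

    @property
    def height(self) -> int:
        return self.planes.shape[1]

    @property
    def width(self) -> int:
        return self.planes.shape[2]


@dataclass
class ChannelImage:
    """One 2-D 8-bit intensity plane extracted from an :class:`RGBStack`."""

    values: np.ndarray
    channel_name: str
    source_path: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("ChannelImage values must be 2-D")
        if self.channel_name not in CHANNEL_NAMES:
            raise ValueError(f"channel_name must be one of {CHANNEL_NAMES}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def read_rgb_stack(path: Union[str, os.PathLike]) -> RGBStack:
    """Read a TIFF file whose pixels carry three color samples.

    16-bit inputs are linearly rescaled to 8 bits by dividing by 257 and
    rounding (257 = 65535/255), which is recorded in the log.  A grayscale or
    single-sample TIFF raises :class:`FormatError` naming the sample count.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"image file not found: {path}")
    arr = tifffile.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 2:
        raise FormatError(
            f"{path}: expected 3 color samples per pixel, found 1 (grayscale)"
        )
    if arr.ndim not in (3, 4) or arr.shape[-1] != 3:
        n_samples = arr.shape[-1] if arr.ndim >= 3 else 1
        raise FormatError(
            f"{path}: expected 3 color samples per pixel, found {n_samples}"
        )
    if arr.dtype == np.uint16:
        log.info("%s: 16-bit input rescaled to 8-bit (value / 257, rounded)", path)
        arr = np.round(arr.astype(np.float64) / 257.0).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise FormatError(f"{path}: unsupported pixel dtype {arr.dtype}")
    return RGBStack(planes=arr, source_path=path)


def write_rgb_stack(path: Union[str, os.PathLike], stack: RGBStack) -> str:
    """Write an :class:`RGBStack` as a baseline interleaved-RGB TIFF."""
    path = os.fspath(path)
    data = stack.planes
    if data.shape[0] == 1:
        data = data[0]
    tifffile.imwrite(path, data, photometric="rgb")
    return path


def split_channels(
    stack: RGBStack, slice_policy: Union[int, str] = "max"
) -> tuple[ChannelImage, ChannelImage, ChannelImage]:
    """Split an RGB stack into red, green and blue planes.

    ``slice_policy`` is either an integer slice index or ``"max"`` for a
    per-channel maximum intensity projection across slices (the default,
    common practice for nuclei in thin tissue).
    """
    if isinstance(slice_policy, int) and not isinstance(slice_policy, bool):
        if not 0 <= slice_policy < stack.n_slices:
            raise ValueError(
                f"slice index {slice_policy} out of range for {stack.n_slices} slices"
            )
        plane = stack.planes[slice_policy]
    elif slice_policy == "max":
        plane = stack.planes.max(axis=0)
    else:
        raise ValueError(f"slice_policy must be an int or 'max', got {slice_policy!r}")
    return tuple(
        ChannelImage(plane[..., i].copy(), CHANNEL_NAMES[i], stack.source_path)
        for i in range(3)
    )


def _fmt(value: float) -> str:
    return f"{value:.6f}"


def write_results_csv(
    rows: Sequence["QuantResult"],
    out_dir: Union[str, os.PathLike],
    image_id: str | None = None,
    summary: "ImageSummary | None" = None,
) -> str:
    """Write per-ROI results plus one per-image summary row as CSV.

    The file contains one header row, one row per ROI and one trailing
    summary row whose ``roi_id`` is the string ``"summary"``.  Because the
    header is fixed, the summary row reuses the ``area_px`` column to carry
    the ROI count, ``mean_raw``/``mean_bg``/``mean_corrected`` to carry the
    per-image means, and leaves the centroid columns empty.  Floats are
    written with 6 decimal places; quoting follows RFC 4180.
    """
    out_dir = os.fspath(out_dir)
    if image_id is None:
        if not rows:
            raise ValueError("image_id is required when the ROI list is empty")
        image_id = rows[0].image_id
    path = os.path.join(out_dir, f"{image_id}_results.csv")
    n = len(rows)
    if summary is not None:
        mean_corr = summary.mean_corrected_mean
        mean_bg = summary.mean_bg
        mean_raw = summary.mean_raw_mean
    else:
        mean_corr = float(np.mean([r.mean_corrected for r in rows])) if rows else float("nan")
        mean_bg = rows[0].mean_bg if rows else float("nan")
        mean_raw = float(np.mean([r.mean_raw for r in rows])) if rows else float("nan")
    try:
        fh = open(path, "w", newline="", encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot write results to {out_dir}: {exc}") from exc
    with fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for r in rows:
            writer.writerow(
                [
                    r.image_id,
                    r.roi_id,
                    r.area_px,
                    _fmt(r.mean_raw),
                    _fmt(r.mean_bg),
                    _fmt(r.mean_corrected),
                    _fmt(r.centroid[0]),
                    _fmt(r.centroid[1]),
                ]
            )
        writer.writerow(
            [
                image_id,
                "summary",
                n,
                _fmt(mean_raw) if n else "",
                _fmt(mean_bg) if n else "",
                _fmt(mean_corr) if n else "",
                "",
                "",
            ]
        )
    return path


def read_results_csv(path: Union[str, os.PathLike]) -> tuple[list[dict], dict]:
    """Parse a results CSV back into ROI-row dicts and the summary-row dict."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        records = list(reader)
    if not records or records[-1]["roi_id"] != "summary":
        raise FormatError(f"{path}: missing summary row")
    return records[:-1], records[-1]
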