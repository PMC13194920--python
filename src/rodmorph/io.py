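"""Label-mask and image-stack I/O, z-projection, and measurement tables.

Label masks are 2D integer images where 0 is background and each positive
integer identifies one cell instance. Labels need not be consecutive.
Coordinates are 0-based (row, column). Pixel size is isotropic, in µm/px.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio

#: Default pixel size (µm/px) used when the caller does not supply one.
#: 65 nm matches typical 100x widefield fluorescence sampling.
DEFAULT_PIXEL_SIZE = 0.065

#: Exact column order of the measurement CSV.
MEASUREMENT_COLUMNS = [
    "image_id",
    "cell_label",
    "length_um",
    "mean_width_um",
    "surface_um2",
    "volume_um3",
    "cross_section_um2",
    "convex_hull_um2",
    "eccentricity",
    "solidity",
    "branched",
    "degenerate",
    "border_touching",
]


class MaskFormatError(ValueError):
    """Raised when an image file cannot be interpreted as an integer label mask."""


@dataclass
class LabelMask:
    """A 2D instance-label image with pixel-size metadata.

    Parameters
    ----------
    labels : ndarray of int, shape (H, W)
        0 = background; positive integers = cell instances.
    pixel_size : float
        µm per pixel, isotropic; must be positive.
    source_path : str
        Provenance string (file path or synthetic tag).
    """

    labels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE
    source_path: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or min(self.labels.shape) < 1:
            raise ValueError("labels must be a non-empty 2D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise MaskFormatError("label image must contain integer values")
        if self.labels.min() < 0:
            raise ValueError("label values must be non-negative")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def instance_labels(self) -> np.ndarray:
        """Sorted array of distinct positive labels present in the mask."""
        values = np.unique(self.labels)
        return values[values > 0]

    @property
    def n_instances(self) -> int:
        return int(self.instance_labels.size)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class ImageStack:
    """An ordered z-stack of equally shaped 2D intensity planes."""

    planes: np.ndarray  # (Z, H, W)
    pixel_size: float = DEFAULT_PIXEL_SIZE
    z_spacing: float | None = None

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=float)
        if self.planes.ndim == 2:
            self.planes = self.planes[None]
        if self.planes.ndim != 3 or self.planes.shape[0] < 1:
            raise ValueError("stack needs at least one 2D plane")
        if not np.all(np.isfinite(self.planes)):
            raise ValueError("stack intensities must be finite")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_planes(self) -> int:
        return self.planes.shape[0]


@dataclass
class MeasurementTable:
    """Per-cell measurement rows keyed by (image_id, cell_label)."""

    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=MEASUREMENT_COLUMNS))

    def __post_init__(self) -> None:
        for col in MEASUREMENT_COLUMNS:
            if col not in self.data.columns:
                self.data[col] = pd.Series(dtype=float)
        self.data = self.data[MEASUREMENT_COLUMNS]
        if self.data.duplicated(["image_id", "cell_label"]).any():
            raise ValueError("(image_id, cell_label) pairs must be unique")

    def __len__(self) -> int:
        return len(self.data)


def read_label_mask(path: str | os.PathLike, pixel_size: float = DEFAULT_PIXEL_SIZE) -> LabelMask:
    """Read a single-plane TIFF or PNG of integer instance labels.

    Values are preserved exactly. Float-valued pixel data raises
    :class:`MaskFormatError`; the file holding labels must be an integer type.
    """
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    if arr.ndim != 2:
        raise MaskFormatError(f"expected a single-plane 2D label image, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise MaskFormatError(f"label image must be integer-typed, got {arr.dtype}")
    return LabelMask(labels=arr.astype(np.int64), pixel_size=pixel_size, source_path=path)


def write_label_mask(mask: LabelMask, path: str | os.PathLike) -> None:
    """Write a label mask as 16-bit TIFF (or PNG by extension)."""
    path = os.fspath(path)
    max_label = int(mask.labels.max(initial=0))
    dtype = np.uint16 if max_label < 2**16 else np.int32
    arr = mask.labels.astype(dtype)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def read_image_stack(path: str | os.PathLike, pixel_size: float = DEFAULT_PIXEL_SIZE,
                     z_spacing: float | None = None) -> ImageStack:
    """Read a multi-page TIFF as a z-stack; plane order = page order."""
    arr = tifffile.imread(os.fspath(path))
    return ImageStack(planes=np.atleast_3d(arr) if arr.ndim == 2 else arr,
                      pixel_size=pixel_size, z_spacing=z_spacing)


def write_image_stack(stack: ImageStack, path: str | os.PathLike) -> None:
    tifffile.imwrite(os.fspath(path), np.asarray(stack.planes, dtype=np.float32))


def project_stack(stack: ImageStack, mode: str = "max") -> np.ndarray:
    """Reduce a z-stack to a single plane by per-pixel max, mean, or sum.

    Raw intensities are reduced without normalization; ``sum`` therefore
    equals ``n_planes × mean`` elementwise.
    """
    reducers = {"max": np.max, "mean": np.mean, "sum": np.sum}
    if mode not in reducers:
        raise ValueError(f"unknown projection mode {mode!r}; choose from {sorted(reducers)}")
    return reducers[mode](stack.planes, axis=0)


def filter_border_labels(mask: LabelMask) -> LabelMask:
    """Remove every instance with at least one pixel on the image border.

    Truncated cells at the field-of-view edge carry biased size estimates;
    this implements the standard curation rule of dropping them. Idempotent.
    """
    labels = mask.labels
    border = np.concatenate([
        labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]
    ])
    touching = np.unique(border[border > 0])
    out = labels.copy()
    if touching.size:
        out[np.isin(out, touching)] = 0
    return LabelMask(labels=out, pixel_size=mask.pixel_size, source_path=mask.source_path)


def border_touching_labels(mask: LabelMask) -> set[int]:
    """Labels having at least one pixel on the first/last row or column."""
    labels = mask.labels
    border = np.concatenate([
        labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]
    ])
    return set(int(v) for v in np.unique(border[border > 0]))


def write_measurement_table(table: MeasurementTable, path: str | os.PathLike) -> None:
    """Write the measurement table as CSV with the canonical column order.

    Floats are written with enough digits that a round trip reproduces
    values to better than 1e-6 relative.
    """
    table.data.to_csv(os.fspath(path), index=False, float_format="%.9g")


def read_measurement_table(path: str | os.PathLike) -> MeasurementTable:
    df = pd.read_csv(os.fspath(path))
    for col in ("branched", "degenerate", "border_touching"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return MeasurementTable(data=df)
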