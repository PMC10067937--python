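"""Physical-unit image container and TIFF I/O.

Every spatial operator in this package works in micrometres.  An
:class:`Image` couples a 2-D intensity raster with the physical pixel
size so downstream code never has to guess the calibration.

Coordinate convention: pixel ``(row, col)`` has its *centre* at the
physical location ``(x, y) = ((col + 0.5) * pixel_size,
(row + 0.5) * pixel_size)``, with 0-based indices.  All exported
coordinates are in µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile


@dataclass
class Image:
    """A 2-D nonnegative intensity raster with physical pixel size.

    Parameters
    ----------
    raster : ndarray
        2-D array of finite, nonnegative intensities.
    pixel_size : float
        Physical size of one pixel, µm/pixel. Must be positive.
    channel_label : str
        Free-text channel name (e.g. ``"PIEZO1"``).
    """

    raster: np.ndarray
    pixel_size: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=float)
        if self.raster.ndim != 2:
            raise ValueError(f"raster must be 2-D, got ndim={self.raster.ndim}")
        if not np.all(np.isfinite(self.raster)):
            raise ValueError("raster contains non-finite values")
        if np.any(self.raster < 0):
            raise ValueError("raster contains negative intensities")
        if not (np.isfinite(self.pixel_size) and self.pixel_size > 0):
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.raster.shape

    @property
    def height_um(self) -> float:
        return self.raster.shape[0] * self.pixel_size

    @property
    def width_um(self) -> float:
        return self.raster.shape[1] * self.pixel_size

    def with_raster(self, raster: np.ndarray) -> "Image":
        """Copy of this image with a new raster, same calibration."""
        return replace(self, raster=raster)

    def pixel_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) physical coordinates of every pixel centre, µm."""
        rows, cols = np.indices(self.raster.shape)
        return (cols + 0.5) * self.pixel_size, (rows + 0.5) * self.pixel_size


def px_to_um(rows: np.ndarray, cols: np.ndarray, pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Map 0-based pixel indices to physical pixel-centre coordinates (x, y) in µm."""
    return (np.asarray(cols) + 0.5) * pixel_size, (np.asarray(rows) + 0.5) * pixel_size


def um_to_px(x: np.ndarray, y: np.ndarray, pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Map physical coordinates (µm) to fractional (row, col) pixel indices."""
    return np.asarray(y) / pixel_size - 0.5, np.asarray(x) / pixel_size - 0.5


def write_tiff(path, image: Image, dtype=None) -> None:
    """Write an image as TIFF with pixel-size (resolution) metadata.

    The resolution tags store pixels-per-µm so the calibration round-trips
    through :func:`read_tiff` and is understood by ImageJ/Fiji.
    """
    data = image.raster
    if dtype is not None:
        data = data.astype(dtype)
    else:
        data = data.astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        resolution=(1.0 / image.pixel_size, 1.0 / image.pixel_size),
        metadata={"unit": "um", "channel_label": image.channel_label},
    )


def read_tiff(path, pixel_size: float | None = None, channel_label: str = "") -> Image:
    """Read a 2-D TIFF; recover pixel size from resolution tags if present.

    An explicit ``pixel_size`` overrides file metadata; if the file carries
    no resolution tag it is required.
    """
    import json as _json

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        if pixel_size is None:
            # trust the resolution tags only when a physical unit is declared
            # (tifffile stamps a placeholder (1, 1) resolution on bare writes)
            unit_tag = page.tags.get("ResolutionUnit")
            has_unit = unit_tag is not None and int(unit_tag.value) > 1
            if not has_unit and page.description:
                try:
                    has_unit = "unit" in _json.loads(page.description)
                except (ValueError, TypeError):
                    has_unit = False
            tag = page.tags.get("XResolution")
            if has_unit and tag is not None:
                num, den = tag.value
                if num > 0:
                    pixel_size = den / num
        if pixel_size is None:
            raise ValueError(
                f"{path}: no resolution metadata; pass pixel_size explicitly"
            )
    return Image(raster=np.asarray(data, dtype=float), pixel_size=float(pixel_size),
                 channel_label=channel_label)
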