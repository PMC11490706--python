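"""Core raster containers and TIFF input/output.

Conventions
-----------
* Axis order is ``(z, y, x)`` for stacks and ``(y, x)`` for single planes.
* Physical scale is carried as ``pixel_size_um`` (micrometres per pixel),
  assumed isotropic in x and y.
* Point coordinates elsewhere in the package are ``(x, y)`` in micrometres;
  pixel ``(row, col)`` corresponds to ``(y / pixel_size, x / pixel_size)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """A 2D image or 3D z-stack of nonnegative intensities with physical scale.

    Parameters
    ----------
    pixels : ndarray
        ``(y, x)`` or ``(z, y, x)`` array of intensities, all >= 0.
    pixel_size_um : float
        Lateral pixel size in micrometres per pixel (> 0).
    channel_label : str
        Free-text marker name (e.g. ``"ZO1"``).
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError(f"pixels must be 2D or 3D, got ndim={self.pixels.ndim}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.pixels.size and float(self.pixels.min()) < 0:
            raise ValueError("intensities must be nonnegative")

    @property
    def is_stack(self) -> bool:
        return self.pixels.ndim == 3

    @property
    def n_slices(self) -> int:
        return self.pixels.shape[0] if self.is_stack else 1

    @property
    def plane_shape(self) -> tuple[int, int]:
        return tuple(self.pixels.shape[-2:])


@dataclass
class BinaryMask:
    """A boolean raster aligned to an image plane, with operation provenance."""

    pixels: np.ndarray
    pixel_size_um: float
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("BinaryMask pixels must be 2D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    def with_step(self, pixels: np.ndarray, step: str) -> "BinaryMask":
        """Return a new mask with ``step`` appended to the provenance."""
        return BinaryMask(pixels, self.pixel_size_um, [*self.provenance, step])

    @property
    def area_um2(self) -> float:
        return float(self.pixels.sum()) * self.pixel_size_um**2


def read_image(
    path: str | Path, pixel_size_um: float | None = None, channel_label: str = ""
) -> ImageStack:
    """Read a single- or multi-page TIFF as an :class:`ImageStack`.

    The pixel size is taken from the TIFF resolution tags (assumed to be in
    pixels per micrometre, as written by :func:`write_image`) unless
    ``pixel_size_um`` is given, which always wins.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        if pixel_size_um is None:
            try:
                xres = tif.pages[0].tags["XResolution"].value
                pixel_size_um = float(xres[1]) / float(xres[0])
            except (KeyError, ZeroDivisionError, TypeError):
                raise ValueError(
                    f"{path}: no resolution metadata; pass pixel_size_um explicitly"
                )
    data = np.squeeze(np.asarray(data))
    return ImageStack(data, pixel_size_um=pixel_size_um, channel_label=channel_label)


def write_image(path: str | Path, stack: ImageStack) -> None:
    """Write an :class:`ImageStack` to TIFF with pixels-per-μm resolution tags.

    Output is deterministic: no timestamps or environment-dependent metadata
    are embedded.
    """
    tifffile.imwrite(
        str(path),
        np.asarray(stack.pixels),
        resolution=(1.0 / stack.pixel_size_um, 1.0 / stack.pixel_size_um),
        metadata=None,
    )


def write_mask(path: str | Path, mask: BinaryMask, sidecar: bool = True) -> None:
    """Write a mask as an 8-bit TIFF plus an optional provenance sidecar JSON."""
    out = ImageStack(mask.pixels.astype(np.uint8) * 255, mask.pixel_size_um)
    write_image(path, out)
    if sidecar:
        meta = {
            "pixel_size_um": mask.pixel_size_um,
            "provenance": mask.provenance,
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2, sort_keys=True))
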