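"""Raw stack → binary junction mask.

The mask pipeline mirrors the standard confocal junction-marker workflow:
maximum intensity projection, Triangle ("Dark") auto-threshold, binary
dilation, and median smoothing of the mask.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .errors import DegenerateHistogram
from .image import BinaryMask, ImageStack

__all__ = [
    "max_project",
    "triangle_threshold",
    "apply_threshold",
    "dilate_mask",
    "median_smooth",
    "make_junction_mask",
]

_STRUCTURES = {
    "square3": np.ones((3, 3), dtype=bool),
    "cross3": np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
}


def max_project(stack: ImageStack) -> ImageStack:
    """Per-pixel maximum across z; identity on 2D input (hence idempotent)."""
    if stack.pixels.size == 0:
        raise ValueError("empty stack")
    pixels = stack.pixels if not stack.is_stack else stack.pixels.max(axis=0)
    return ImageStack(np.array(pixels), stack.pixel_size_um, stack.channel_label)


def _histogram(pixels: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Counts and bin values.

    Integer-valued images (integer dtype, or floats holding whole numbers,
    e.g. photon counts) get native integer bins up to 65536 so that sparse
    levels never alias into artificially empty bins; other float images are
    min–max scaled into ``n_bins`` equal bins addressed by their centers.
    """
    flat = pixels.ravel()
    lo, hi = float(flat.min()), float(flat.max())
    integral = np.issubdtype(pixels.dtype, np.integer) or bool(
        np.all(np.equal(np.mod(flat, 1), 0))
    )
    if integral and (hi - lo) < 65536:
        values = np.arange(int(lo), int(hi) + 1)
        counts = np.bincount(
            (flat - int(lo)).astype(np.int64), minlength=len(values)
        )
        return counts.astype(np.int64), values.astype(float)
    counts, edges = np.histogram(flat, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts.astype(np.int64), centers


def triangle_threshold(
    image: ImageStack | np.ndarray, dark_background: bool = True, n_bins: int = 256
) -> float:
    """Triangle (Zack) auto-threshold on the intensity histogram.

    Geometric construction: a straight line joins the histogram peak to the
    far tail bin on the object side (the brightest occupied bin under the
    dark-background convention); the threshold is the bin between them whose
    histogram point is farthest from that line.  Ties resolve to the lowest
    such bin.  Pixels strictly above the returned value are foreground.

    Raises
    ------
    DegenerateHistogram
        For constant images or histograms with fewer than two occupied bins.
    """
    pixels = image.pixels if isinstance(image, ImageStack) else np.asarray(image)
    counts, values = _histogram(pixels, n_bins)
    occupied = np.flatnonzero(counts)
    if len(occupied) < 2:
        raise DegenerateHistogram("histogram has fewer than two occupied bins")
    if not dark_background:
        # Mirror so the construction always runs peak → bright tail.
        counts = counts[::-1]
        values = values[::-1]
        occupied = np.flatnonzero(counts)
    peak = int(np.argmax(counts))  # argmax ties → lowest bin
    tail = int(occupied[-1])
    if tail <= peak:
        raise DegenerateHistogram("no object-side tail beyond the histogram peak")
    idx = np.arange(peak, tail + 1)
    h = counts[idx].astype(float)
    # Perpendicular distance from (i, h_i) to the peak–tail line.
    dx = float(tail - peak)
    dh = float(counts[tail] - counts[peak])
    dist = np.abs(dh * (idx - peak) - dx * (h - counts[peak])) / np.hypot(dx, dh)
    interior = dist[1:-1]
    if len(interior) == 0:
        return float(values[peak])
    best = int(idx[1:-1][np.argmax(interior)])  # argmax ties → lowest bin
    return float(values[best])


def apply_threshold(
    image: ImageStack, threshold: float, dark_background: bool = True
) -> BinaryMask:
    """Foreground = pixels strictly above (dark bg) / below (bright bg)."""
    fg = image.pixels > threshold if dark_background else image.pixels < threshold
    return BinaryMask(
        fg, image.pixel_size_um, [f"threshold({threshold:.6g}, dark={dark_background})"]
    )


def dilate_mask(
    mask: BinaryMask, iterations: int = 1, structuring_element: str = "square3"
) -> BinaryMask:
    """Iterated binary dilation; extensive (output ⊇ input), identity at 0."""
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    structure = _STRUCTURES[structuring_element]
    pixels = mask.pixels
    if iterations > 0:
        pixels = ndi.binary_dilation(pixels, structure=structure, iterations=iterations)
    return mask.with_step(pixels, f"dilate({iterations}, {structuring_element})")


def _disk_footprint(radius_px: float) -> np.ndarray:
    r = int(np.floor(radius_px))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2) <= radius_px**2


def median_smooth(mask: BinaryMask, radius_px: float) -> BinaryMask:
    """Binary median (disk-majority) filter.

    Each pixel takes the majority value over the Euclidean disk of the given
    radius, clipped at the image border; an exact tie counts as foreground.
    Removes isolated specks and smooths the mask contour.
    """
    if radius_px <= 0:
        raise ValueError("radius_px must be positive")
    fp = _disk_footprint(radius_px).astype(np.int64)
    fg = ndi.convolve(mask.pixels.astype(np.int64), fp, mode="constant", cval=0)
    total = ndi.convolve(np.ones_like(fg), fp, mode="constant", cval=0)
    return mask.with_step(2 * fg >= total, f"median_smooth(r={radius_px})")


def make_junction_mask(
    stack: ImageStack,
    dark_background: bool = True,
    n_bins: int = 256,
    dilate_iterations: int = 1,
    structuring_element: str = "square3",
    median_radius_px: float = 12.0,
) -> BinaryMask:
    """Full preprocessing chain: project → threshold → dilate → median."""
    projected = max_project(stack)
    t = triangle_threshold(projected, dark_background=dark_background, n_bins=n_bins)
    mask = apply_threshold(projected, t, dark_background=dark_background)
    mask.provenance.insert(0, "max_project")
    mask = dilate_mask(mask, dilate_iterations, structuring_element)
    if median_radius_px > 0:
        mask = median_smooth(mask, median_radius_px)
    return mask
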