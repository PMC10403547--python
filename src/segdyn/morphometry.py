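"""Spheroid-compaction morphometry from phase-contrast time lapse.

During multicellular aggregation a cell suspension compacts into a
spheroid; the degree of compaction is read out as the shrinking perimeter
of the spheroid footprint over time, normalised to the first frame.  The
segmentation pipeline mirrors the standard phase-contrast workflow: Sobel
edge enhancement (the bright halo gives a strong gradient ridge at the
spheroid boundary), a 5 px Gaussian blur, IsoData (iterative intermeans)
thresholding, filling of holes below 1000 px, and selection of the largest
connected component.  The selected component is then solidified (all
enclosed holes filled) and its outer contour measured at sub-pixel
resolution, giving the perimeter of the spheroid footprint in µm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters as skfilters
from skimage import measure as skmeasure
from skimage import morphology as skmorph


class NoObjectError(ValueError):
    """Raised when a frame contains no segmentable foreground object."""


@dataclass
class FrameImage:
    """Single 2D phase-contrast frame with physical pixel size (µm)."""

    pixels: np.ndarray
    pixel_size: float
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class SpheroidMask:
    """Segmented spheroid footprint (single solid component) + provenance."""

    mask: np.ndarray
    threshold: float
    holes_filled: int
    component_area_px: int


@dataclass
class SpheroidTrace:
    """Perimeter time series, absolute (µm) and as % of the first frame."""

    times: np.ndarray
    perimeter_um: np.ndarray
    perimeter_pct: np.ndarray


def preprocess_frame(frame: FrameImage, blur_sigma_px: float = 5.0) -> FrameImage:
    """Sobel gradient magnitude followed by Gaussian smoothing.

    The Sobel magnitude √(Gx² + Gy²) is computed with a reflective border,
    then blurred with an isotropic Gaussian of the given sigma (default
    5 px).  Output is a new frame; pixel size and timestamp carry over.
    """
    img = frame.pixels
    if min(img.shape) < 16:
        raise ValueError("frame must be at least 16x16 px")
    gx = ndimage.sobel(img, axis=1, mode="reflect")
    gy = ndimage.sobel(img, axis=0, mode="reflect")
    grad = np.sqrt(gx**2 + gy**2)
    if blur_sigma_px > 0:
        grad = ndimage.gaussian_filter(grad, blur_sigma_px, mode="reflect")
    return FrameImage(grad, frame.pixel_size, frame.timestamp)


def isodata_threshold(image: np.ndarray, tol: float = 0.5, max_iter: int = 200) -> float:
    """Iterative intermeans (Ridler–Calvard / IsoData) threshold.

    Starting from the mid-range, iterate T ← (mean below T + mean above T)/2
    until the update is below ``tol`` (in intensity units) or a fixed point
    is reached.  The converged T lies strictly between the image minimum
    and maximum.  A constant image has no separable classes and raises.
    """
    vals = np.asarray(image, dtype=np.float64).ravel()
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        raise ValueError("constant image: IsoData threshold undefined")
    T = (lo + hi) / 2.0
    for _ in range(max_iter):
        below = vals[vals <= T]
        above = vals[vals > T]
        if below.size == 0:
            m_below = lo
        else:
            m_below = float(below.mean())
        if above.size == 0:
            m_above = hi
        else:
            m_above = float(above.mean())
        T_new = (m_below + m_above) / 2.0
        if abs(T_new - T) < tol:
            T = T_new
            break
        T = T_new
    return float(np.clip(T, np.nextafter(lo, hi), np.nextafter(hi, lo)))


def _fill_small_holes(mask: np.ndarray, hole_limit_px: int) -> tuple[np.ndarray, int]:
    """Fill enclosed background holes strictly smaller than the limit."""
    # max_size fills holes <= its value; the protocol fills holes < limit.
    filled = skmorph.remove_small_holes(mask, max_size=hole_limit_px - 1)
    n_holes = 0
    if filled.sum() != mask.sum():
        holes = filled & ~mask
        n_holes = int(ndimage.label(holes, structure=np.ones((3, 3)))[1])
    return filled, n_holes


def segment_spheroid(
    frame: FrameImage,
    hole_limit_px: int = 1000,
    blur_sigma_px: float = 5.0,
    solid: bool = True,
) -> SpheroidMask:
    """Segment the spheroid footprint from one phase-contrast frame.

    Pipeline: preprocess → IsoData threshold → fill holes < hole_limit_px
    → select largest 8-connected component → (by default) fill all
    remaining enclosed holes so the mask is the solid footprint.  With
    ``solid=False`` the raw thresholded edge band of the largest component
    is returned instead.

    Raises :class:`NoObjectError` on an empty foreground.  Equal-area
    component ties break deterministically towards the component whose
    minimal (row, col) pixel is lexicographically smallest.
    """
    pre = preprocess_frame(frame, blur_sigma_px)
    try:
        thr = isodata_threshold(pre.pixels)
    except ValueError:
        raise NoObjectError("frame has constant preprocessed intensity") from None
    fg = pre.pixels > thr
    if not fg.any():
        raise NoObjectError("no foreground above threshold")
    fg, n_holes = _fill_small_holes(fg, hole_limit_px)

    labels, n = ndimage.label(fg, structure=np.ones((3, 3)))  # 8-connectivity
    if n == 0:
        raise NoObjectError("no connected component found")
    areas = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    best_area = areas.max()
    candidates = np.flatnonzero(areas == best_area) + 1
    if len(candidates) > 1:
        # Tie-break on the lexicographically smallest (row, col) pixel.
        firsts = []
        flat = labels.ravel()
        for lab in candidates:
            firsts.append(np.flatnonzero(flat == lab)[0])
        winner = candidates[int(np.argmin(firsts))]
    else:
        winner = candidates[0]
    comp = labels == winner
    if solid:
        comp = ndimage.binary_fill_holes(comp)
    return SpheroidMask(
        mask=comp,
        threshold=thr,
        holes_filled=n_holes,
        component_area_px=int(comp.sum()),
    )


def measure_perimeter(
    mask: SpheroidMask | np.ndarray,
    pixel_size: float,
    smooth_sigma_px: float = 1.0,
) -> float:
    """Sub-pixel outer-contour length of a single-component mask, in µm.

    The boolean mask is lightly smoothed (Gaussian, default σ = 1 px) and
    its 0.5 level set traced by marching squares; the longest closed
    contour is the outer boundary and its polygonal length times the pixel
    size is returned.  The light smoothing suppresses the pixelation
    excess of the digitised boundary without erasing physical roughness on
    scales above a couple of pixels.
    """
    arr = mask.mask if isinstance(mask, SpheroidMask) else np.asarray(mask, bool)
    if not arr.any():
        raise ValueError("empty mask has no perimeter")
    n_comp = ndimage.label(arr, structure=np.ones((3, 3)))[1]
    if n_comp != 1:
        raise ValueError(f"mask must have exactly one component, found {n_comp}")
    f = np.pad(arr.astype(np.float64), 2)
    if smooth_sigma_px > 0:
        f = ndimage.gaussian_filter(f, smooth_sigma_px)
    contours = skmeasure.find_contours(f, 0.5)
    if not contours:
        raise ValueError("no contour found at the 0.5 level")
    lengths = [
        float(np.sum(np.sqrt((np.diff(c, axis=0) ** 2).sum(axis=1)))) for c in contours
    ]
    return max(lengths) * pixel_size


def perimeter_series(
    frames: list[FrameImage],
    hole_limit_px: int = 1000,
    blur_sigma_px: float = 5.0,
) -> SpheroidTrace:
    """Per-frame segmentation and perimeter, normalised to frame 0.

    Frames that fail segmentation are recorded as NaN; the first frame
    must segment (it provides the normaliser).
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    perims = np.full(len(frames), np.nan)
    for i, fr in enumerate(frames):
        try:
            m = segment_spheroid(fr, hole_limit_px, blur_sigma_px)
            perims[i] = measure_perimeter(m, fr.pixel_size)
        except (NoObjectError, ValueError):
            if i == 0:
                raise NoObjectError("first frame failed to segment; no normaliser")
    times = np.array([fr.timestamp for fr in frames], dtype=float)
    pct = 100.0 * perims / perims[0]
    return SpheroidTrace(times=times, perimeter_um=perims, perimeter_pct=pct)
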