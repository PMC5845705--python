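"""Marker-controlled watershed segmentation of neuronal somata.

Fluorescence frames are averaged in blocks of 50 and min-max scaled; a
foreground marker is derived per soma by a morphological top-hat / regional-
maxima sequence, a background marker network from the watershed ridge lines
of the Euclidean distance transform of the Otsu-binarized image, and the
final segmentation floods the Sobel gradient magnitude with minima imposed
at both marker sets (Meyer watershed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.segmentation import watershed

from ._filters import minmax_scale
from .containers import FluorescenceMovie


@dataclass
class SegParams:
    frames_to_average: int = 50
    #: stride between averaged blocks; None = frames_to_average (non-overlapping)
    stride: int | None = None
    marker_opening_radius: int = 6
    erosion_disk_radius: int = 2
    #: tolerance below a regional peak that still counts as the peak plateau;
    #: genuine soma maxima form plateaus wide enough to survive the 3x3
    #: marker opening while single-pixel noise maxima do not
    maxima_h: float = 0.45
    #: high-intensity threshold for candidate markers, on the [0, 1] scale of
    #: the eroded top-hat residual; rejects plateau maxima of pure noise
    marker_min_intensity: float = 0.1
    background_dilation_radius: int = 2
    #: constant substituted at foreground pixels before Otsu ("median" or float)
    fg_fill: str | float = "median"

    def __post_init__(self) -> None:
        if self.frames_to_average < 1:
            raise ValueError("frames_to_average must be >= 1")
        if min(self.marker_opening_radius, self.erosion_disk_radius, self.background_dilation_radius) < 1:
            raise ValueError("structuring-element radii must be >= 1")


@dataclass
class Segmentation:
    """Label image (0 = background / watershed line) with region summaries."""

    labels: np.ndarray
    centroids: np.ndarray  # (n_regions, 2) as (row, col)
    region_ids: np.ndarray

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def region_pixels(self, region_id: int) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(self.labels == region_id)


def preprocess_frames(movie: FluorescenceMovie, params: SegParams | None = None) -> np.ndarray:
    """Block-averaged, min-max scaled reference images, shape (blocks, H, W).

    Averages ``frames_to_average`` consecutive frames (non-overlapping by
    default) and scales each averaged image to [0, 1]; a constant image maps
    to all zeros. A trailing partial block is dropped.
    """
    params = params or SegParams()
    data = movie.data
    if data.shape[0] == 0:
        raise ValueError("empty movie")
    if data.shape[0] < params.frames_to_average:
        raise ValueError(
            f"movie has {data.shape[0]} frames, fewer than frames_to_average={params.frames_to_average}"
        )
    k = params.frames_to_average
    stride = params.stride or k
    starts = range(0, data.shape[0] - k + 1, stride)
    out = np.stack([data[s : s + k].mean(axis=0, dtype=np.float64) for s in starts])
    return np.stack([minmax_scale(img) for img in out])


def foreground_markers(image: np.ndarray, params: SegParams | None = None) -> np.ndarray:
    """Binary soma-marker mask from one preprocessed image.

    Pipeline: morphological opening with a disk of ``marker_opening_radius``
    (removes soma-scale bright objects) -> top-hat residual (image minus
    opening) -> grayscale erosion with a disk of radius 2 -> regional maxima
    (with plateau tolerance ``maxima_h``) -> binary erosion then dilation
    with a 3x3 neighborhood to discard speckle maxima.
    """
    params = params or SegParams()
    image = np.asarray(image, dtype=float)
    opened = morphology.opening(image, morphology.disk(params.marker_opening_radius))
    residual = image - opened
    eroded = morphology.erosion(residual, morphology.disk(params.erosion_disk_radius))
    if eroded.max() <= 0:
        return np.zeros_like(image, dtype=bool)
    # Regional maxima with plateau tolerance: every pixel within maxima_h of
    # its regional peak (the h-dome of a grayscale reconstruction). Exact
    # maxima of a smooth image are single pixels, which the 3x3 opening
    # below would annihilate; the tolerance restores the plateau extent that
    # quantized real images have.
    recon = morphology.reconstruction(eroded - params.maxima_h, eroded, method="dilation")
    # high-intensity objects only: erosion plateaus of pure noise also form
    # regional maxima, but sit far below the soma residual level
    maxima = ((eroded - recon) > 1e-9) & (eroded > params.marker_min_intensity)
    square = np.ones((3, 3), dtype=bool)
    mask = morphology.erosion(maxima, square)
    mask = morphology.dilation(mask, square)
    return mask


def background_markers(
    image: np.ndarray, fg_mask: np.ndarray, params: SegParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Background-marker mask separating somata; returns ``(bg, fg)``.

    Foreground pixels are equalized to a constant (image median by default),
    the image Otsu-binarized, and the watershed ridge lines of the Euclidean
    distance transform of that binary image taken as background markers.
    Markers are dilated by a disk of radius 2 and any overlap removed from
    the foreground mask so the two marker sets never touch.

    A degenerate (constant) image yields an all-border background marker and
    a warning.
    """
    params = params or SegParams()
    image = np.asarray(image, dtype=float)
    fg_mask = np.asarray(fg_mask, dtype=bool)
    if fg_mask.shape != image.shape:
        raise ValueError("fg_mask shape must match image")
    filled = image.copy()
    fill_value = float(np.median(image)) if params.fg_fill == "median" else float(params.fg_fill)
    filled[fg_mask] = fill_value

    try:
        if np.ptp(filled) == 0:
            raise ValueError("constant image")
        thr = threshold_otsu(filled)
    except ValueError:
        warnings.warn("degenerate image for Otsu thresholding; using border background markers")
        bg = np.zeros_like(fg_mask)
        bg[0, :] = bg[-1, :] = bg[:, 0] = bg[:, -1] = True
        return bg, fg_mask & ~bg

    binary = filled > thr
    dist = ndi.distance_transform_edt(binary)
    ridge_labels = watershed(dist, watershed_line=True)
    bg = ridge_labels == 0
    bg = morphology.dilation(bg, morphology.disk(params.background_dilation_radius))
    fg = fg_mask & ~bg
    return bg, fg


def _sobel_gradient(image: np.ndarray) -> np.ndarray:
    """Gradient magnitude from the Sobel horizontal filter and its transpose,
    replicate padding at the borders."""
    gx = ndi.sobel(image, axis=1, mode="nearest")
    gy = ndi.sobel(image, axis=0, mode="nearest")
    return np.hypot(gx, gy)


def watershed_segment(
    image: np.ndarray,
    fg_mask: np.ndarray,
    bg_mask: np.ndarray,
    params: SegParams | None = None,
) -> Segmentation:
    """Meyer watershed of the Sobel gradient with imposed marker minima.

    Regions grown from background markers become label 0; the remaining
    regions are relabeled 1..K with intensity-unweighted centroids.
    An empty foreground mask yields an empty segmentation.
    """
    image = np.asarray(image, dtype=float)
    fg_mask = np.asarray(fg_mask, dtype=bool)
    bg_mask = np.asarray(bg_mask, dtype=bool)
    if (fg_mask & bg_mask).any():
        raise ValueError("foreground and background markers must be disjoint")
    if not fg_mask.any():
        return Segmentation(
            labels=np.zeros(image.shape, dtype=np.int32),
            centroids=np.empty((0, 2)),
            region_ids=np.empty(0, dtype=int),
        )

    gradient = _sobel_gradient(image)
    fg_labels = cc_label(fg_mask, connectivity=2)
    markers = np.where(bg_mask, 1, 0) + np.where(fg_labels > 0, fg_labels + 1, 0)
    flooded = watershed(gradient, markers=markers, watershed_line=True)

    labels = np.where(flooded > 1, flooded - 1, 0).astype(np.int32)
    props = regionprops(labels)
    # relabel 1..K in ascending original order
    out = np.zeros_like(labels)
    centroids = []
    ids = []
    for new_id, p in enumerate(props, start=1):
        out[labels == p.label] = new_id
        centroids.append(p.centroid)
        ids.append(new_id)
    return Segmentation(
        labels=out,
        centroids=np.asarray(centroids) if centroids else np.empty((0, 2)),
        region_ids=np.asarray(ids, dtype=int),
    )


def segment_image(image: np.ndarray, params: SegParams | None = None) -> Segmentation:
    """Full marker pipeline + watershed for one preprocessed image."""
    params = params or SegParams()
    fg = foreground_markers(image, params)
    bg, fg = background_markers(image, fg, params)
    return watershed_segment(image, fg, bg, params)


def segment_movie(movie: FluorescenceMovie, params: SegParams | None = None) -> list[Segmentation]:
    """Segment every block-averaged reference image of a movie."""
    params = params or SegParams()
    return [segment_image(img, params) for img in preprocess_frames(movie, params)]
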