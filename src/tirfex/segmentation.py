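"""Focal-adhesion and cell-footprint segmentation.

The FA mask comes from binary thresholding of the integrin channel on the
pre-bleach reference frame (Otsu by default, restricted to the cell
footprint when one is supplied).  The cell footprint is primarily a
manually drawn polygon; an automatic multi-level threshold path is
provided as a convenience for synthetic data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import label as sk_label


@dataclass(frozen=True)
class BinaryMask:
    """A boolean H x W image with its pixel calibration."""

    pixels: np.ndarray
    pixel_size_um: float = 0.189

    def __post_init__(self) -> None:
        if self.pixels.dtype != bool or self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D boolean array")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())


def _as_bool(mask) -> np.ndarray:
    return mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, bool)


def segment_fas(
    reference_frame: np.ndarray,
    threshold: float | str = "otsu",
    min_area_px: int = 8,
    fill_holes: bool = True,
    cell_mask: np.ndarray | BinaryMask | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold the pre-bleach reference frame into an FA label image.

    Parameters
    ----------
    reference_frame:
        2D intensity image (typically the mean of the pre-bleach frames).
    threshold:
        "otsu" for Otsu's method (computed within ``cell_mask`` when
        given), or an explicit numeric threshold.
    min_area_px:
        Components smaller than this are discarded (default 8 px,
        ~0.29 um^2 at 0.189 um/px).
    fill_holes:
        Fill holes inside each FA component.
    cell_mask:
        Optional footprint; pixels outside it are excluded from both the
        threshold estimate and the mask.

    Returns
    -------
    (fa_labels, fa_mask):
        int32 labels 1..K (0 = background) and the boolean mask.
    """
    frame = np.asarray(reference_frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("reference_frame must be 2D")
    if not np.all(np.isfinite(frame)):
        raise ValueError("reference_frame contains non-finite pixels")
    cell = _as_bool(cell_mask) if cell_mask is not None else None

    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold method {threshold!r}")
        sample = frame[cell] if cell is not None else frame.ravel()
        if np.ptp(sample) == 0:
            raise ValueError("constant frame: automatic threshold undefined")
        thr = float(threshold_otsu(sample))
    else:
        thr = float(threshold)
        if thr < frame.min() or thr > frame.max():
            warnings.warn(
                "manual threshold outside frame intensity range", stacklevel=2
            )

    mask = frame > thr
    if cell is not None:
        mask &= cell
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    labels = sk_label(mask, connectivity=2)
    if min_area_px > 1 and labels.max() > 0:
        counts = np.bincount(labels.ravel())
        keep = counts >= min_area_px
        keep[0] = False
        mask = keep[labels]
        labels = sk_label(mask, connectivity=2)
    return labels.astype(np.int32), mask


def polygon_to_mask(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a (row, col) polygon: a pixel is inside when its center
    (integer coordinates) lies inside or on the polygon boundary."""
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise ValueError("polygon needs >= 3 (row, col) vertices")
    poly = Polygon(verts)
    if not poly.is_valid:
        raise ValueError("polygon is self-intersecting or degenerate")
    h, w = shape
    rmin = max(int(np.floor(verts[:, 0].min())), 0)
    rmax = min(int(np.ceil(verts[:, 0].max())), h - 1)
    cmin = max(int(np.floor(verts[:, 1].min())), 0)
    cmax = min(int(np.ceil(verts[:, 1].max())), w - 1)
    mask = np.zeros(shape, dtype=bool)
    if rmax < rmin or cmax < cmin:
        return mask
    rr, cc = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
    pts = shapely.points(rr.ravel().astype(float), cc.ravel().astype(float))
    inside = shapely.covers(poly, pts).reshape(rr.shape)
    mask[rmin : rmax + 1, cmin : cmax + 1] = inside
    return mask


def segment_cell_footprint(
    reference_frame: np.ndarray | None = None,
    polygon_vertices: np.ndarray | None = None,
    pixel_size_um: float = 0.189,
) -> BinaryMask:
    """Cell footprint from a drawn polygon (primary path) or, as a
    convenience, from a multi-level threshold of the reference frame.

    The automatic path splits the frame into three intensity classes
    (extracellular background, cell interior, FAs) and keeps everything
    above the lowest threshold, filled and reduced to the largest
    connected component.
    """
    if polygon_vertices is not None:
        if reference_frame is not None:
            shape = np.asarray(reference_frame).shape
        else:
            verts = np.asarray(polygon_vertices, dtype=float)
            shape = (int(np.ceil(verts[:, 0].max())) + 1,
                     int(np.ceil(verts[:, 1].max())) + 1)
        mask = polygon_to_mask(polygon_vertices, shape)
        if not mask.any():
            raise ValueError("polygon rasterized to an empty mask")
        return BinaryMask(mask, pixel_size_um)
    if reference_frame is None:
        raise ValueError("need a reference frame or polygon vertices")
    frame = np.asarray(reference_frame, dtype=float)
    if np.ptp(frame) == 0:
        raise ValueError("constant frame: automatic footprint undefined")
    thr = threshold_multiotsu(frame, classes=3)[0]
    mask = frame > thr
    mask = ndimage.binary_fill_holes(mask)
    labels = sk_label(mask, connectivity=2)
    if labels.max() == 0:
        raise ValueError("automatic footprint segmentation found nothing")
    largest = 1 + np.argmax(np.bincount(labels.ravel())[1:])
    return BinaryMask(labels == largest, pixel_size_um)
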