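"""Nucleus ROI detection and fluorescence extraction.

Detection cross-correlates a time-averaged image against a Gaussian kernel
sized like an average nucleus (fast normalized cross-correlation), thresholds
the correlation map, and keeps connected components within an area band.
Extraction averages pixel intensity within each ROI per frame.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.feature import match_template

from .containers import FluorescenceMatrix, RoiMask


def _nucleus_kernel(radius_px: int) -> np.ndarray:
    """Gaussian spot template with a footprint of side 2*radius+1."""
    r = int(radius_px)
    sigma = max(r / 1.5, 0.8)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return np.exp(-(xx**2 + yy**2) / (2 * sigma**2))


def detect_nuclei(
    mean_image: np.ndarray,
    kernel_radius_px: int = 4,
    corr_threshold: float = 0.5,
    min_area_px: int = 20,
    max_area_px: int = 400,
    *,
    plane: int = 0,
    pixel_size_um: tuple[float, float] = (1.0, 1.0),
    plane_spacing_um: float = 0.0,
    id_offset: int = 0,
) -> list[RoiMask]:
    """Detect nuclei on one averaged plane image.

    Returns ROIs with centroids mapped to um via ``pixel_size_um`` (x, y per
    pixel) and ``z = plane * plane_spacing_um``. A constant (zero-variance)
    image yields no detections.
    """
    img = np.asarray(mean_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("mean_image must be 2D")
    if not np.all(np.isfinite(img)):
        raise ValueError("mean_image contains non-finite values")
    if kernel_radius_px < 1:
        raise ValueError("kernel_radius_px must be >= 1")
    if img.std() == 0:
        return []

    corr = match_template(img, _nucleus_kernel(kernel_radius_px), pad_input=True)
    corr = np.nan_to_num(corr, nan=0.0, posinf=0.0, neginf=0.0)
    labelled, n_comp = ndimage.label(corr > corr_threshold)
    rois: list[RoiMask] = []
    px_x, px_y = pixel_size_um
    for comp in range(1, n_comp + 1):
        pix = np.argwhere(labelled == comp)
        if not (min_area_px <= len(pix) <= max_area_px):
            continue
        # correlation-weighted centroid: of two merged peaks the stronger wins
        w = corr[pix[:, 0], pix[:, 1]]
        cr = float(np.average(pix[:, 0], weights=w))
        cc = float(np.average(pix[:, 1], weights=w))
        rois.append(
            RoiMask(
                roi_id=id_offset + len(rois),
                plane=plane,
                pixels=pix,
                centroid_um=(cc * px_x, cr * px_y, plane * plane_spacing_um),
            )
        )
    return rois


def detect_nuclei_stack(
    mean_stack: np.ndarray,
    kernel_radius_px: int = 4,
    corr_threshold: float = 0.5,
    min_area_px: int = 20,
    max_area_px: int = 400,
    *,
    pixel_size_um: tuple[float, float] = (1.0, 1.0),
    plane_spacing_um: float = 0.0,
) -> list[RoiMask]:
    """Run detection plane by plane on a (planes, H, W) averaged stack with
    globally unique ROI ids."""
    if mean_stack.ndim != 3:
        raise ValueError("mean_stack must be (planes, H, W)")
    rois: list[RoiMask] = []
    for p in range(mean_stack.shape[0]):
        rois.extend(
            detect_nuclei(
                mean_stack[p],
                kernel_radius_px,
                corr_threshold,
                min_area_px,
                max_area_px,
                plane=p,
                pixel_size_um=pixel_size_um,
                plane_spacing_um=plane_spacing_um,
                id_offset=len(rois),
            )
        )
    return rois


def extract_fluorescence(
    movie: np.ndarray,
    masks: list[RoiMask],
    frame_rate_hz: float = 1.25,
) -> FluorescenceMatrix:
    """Average pixel intensity within each ROI per frame.

    ``movie`` is (frames, planes, H, W) or (frames, H, W) for a single plane.
    Row order follows mask order.
    """
    movie = np.asarray(movie)
    if movie.ndim == 3:
        movie = movie[:, None]
    if movie.ndim != 4:
        raise ValueError("movie must be (frames, planes, H, W)")
    T, P, H, W = movie.shape
    F = np.empty((len(masks), T))
    for i, m in enumerate(masks):
        if not 0 <= m.plane < P:
            raise ValueError(f"ROI {m.roi_id} references missing plane {m.plane}")
        if m.pixels[:, 0].max() >= H or m.pixels[:, 1].max() >= W:
            raise ValueError(f"ROI {m.roi_id} extends beyond frame bounds")
        F[i] = movie[:, m.plane, m.pixels[:, 0], m.pixels[:, 1]].mean(axis=1)
    return FluorescenceMatrix(F=F, frame_rate_hz=frame_rate_hz)
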