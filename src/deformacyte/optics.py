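"""Cell segmentation and moment-based ellipse measurement.

Frames show dark cell outlines on a light background.  The measurement chain
is: contrast rescaling, gradient (Canny) edge detection, contour closing and
hole filling, connected-component filtering, then an ellipse fit from the
second-order central moments of the filled region.  The axis convention is
``4 * sqrt(eigenvalue)`` of the normalised moment matrix with the 1/12
per-pixel variance correction, which returns a disk's diameter for a disk.
Optical deformability (OD) is the major/minor axis ratio; rigid spheres give
OD = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import color, feature, morphology, restoration

from .simkit import AcquisitionSettings, ChannelGeometry, Frame

__all__ = [
    "OpticalMeasurement",
    "SegmentationParams",
    "EllipseFit",
    "OpticalCalibration",
    "preprocess",
    "segment_cell",
    "fit_ellipse_moments",
    "optical_deformability",
    "optical_diameter",
    "calibrate_pixels",
    "measure_frame",
    "measure_frames",
]


@dataclass(frozen=True)
class SegmentationParams:
    sigma: float = 1.4            # Gaussian scale of the edge detector
    min_area_px: int = 25         # reject specks below this area
    closing_radius: int = 2       # bridge small gaps in the edge contour
    low_threshold: float | None = None   # auto from noise when None
    high_threshold: float | None = None
    interior_level: float = 0.5   # 50%-coverage cut refining the boundary


@dataclass
class EllipseFit:
    major_px: float
    minor_px: float
    orientation_rad: float
    centroid_x_px: float   # continuous coords, pixel centres at index + 0.5
    centroid_y_px: float


@dataclass(frozen=True)
class OpticalCalibration:
    """Bead-referenced pixel scale and size normalisation."""

    pixel_scale_um: float
    bead_axis_gm_px_median: float   # median geometric-mean axis of beads, px
    bead_diameter_um: float = 10.0


@dataclass
class OpticalMeasurement:
    frame_index: int
    timestamp_s: float
    centroid_x_px: float
    centroid_y_px: float
    major_px: float
    minor_px: float
    orientation_rad: float
    od: float
    y_um: float
    x_um: float
    n_objects_in_frame: int
    optical_diameter_um: float = float("nan")


def preprocess(frame_image: np.ndarray) -> np.ndarray:
    """Grayscale conversion and percentile (1st-99th) contrast rescaling."""
    arr = np.asarray(frame_image, dtype=float)
    if arr.ndim == 3:
        arr = color.rgb2gray(arr[..., :3])
    elif arr.ndim != 2:
        raise ValueError("frame must be 2-D or RGB")
    p1, p99 = np.percentile(arr, [1, 99])
    if p99 - p1 < 1e-12:
        raise ValueError("constant image: zero dynamic range")
    return np.clip((arr - p1) / (p99 - p1), 0.0, 1.0)


def segment_cell(image: np.ndarray,
                 params: SegmentationParams | None = None,
                 ) -> tuple[np.ndarray | None, int]:
    """Edge-based segmentation; returns (largest mask or None, object count).

    Hysteresis thresholds default to multiples of the estimated pixel-noise
    SD.  Components touching the left/right frame edge (cells partially
    outside the capture window) are excluded; the count covers every
    surviving component so multi-cell frames can be routed to coincidence
    handling instead of being silently measured.
    """
    if params is None:
        params = SegmentationParams()
    noise = float(restoration.estimate_sigma(image))
    high = params.high_threshold
    if high is None:
        high = max(0.08, 3.0 * noise)
    low = params.low_threshold
    if low is None:
        low = 0.5 * high

    edges = feature.canny(image, sigma=params.sigma,
                          low_threshold=low, high_threshold=high)
    closed = morphology.closing(edges, morphology.disk(params.closing_radius))
    filled = ndi.binary_fill_holes(closed)
    # the canny line straddles the outline; cut back to the 50%-coverage
    # isophote so the mask tracks the true boundary, then re-fill
    filled &= image < params.interior_level
    filled = ndi.binary_fill_holes(filled)
    labels, n_lab = ndi.label(filled)
    if n_lab == 0:
        return None, 0

    w = image.shape[1]
    keep = []
    for lab in range(1, n_lab + 1):
        mask = labels == lab
        area = int(mask.sum())
        if area < params.min_area_px:
            continue
        cols = np.nonzero(mask.any(axis=0))[0]
        if cols[0] == 0 or cols[-1] == w - 1:
            continue
        keep.append((area, lab))
    if not keep:
        return None, 0
    keep.sort(reverse=True)
    return labels == keep[0][1], len(keep)


def fit_ellipse_moments(mask: np.ndarray) -> EllipseFit:
    """Ellipse from normalised second-order central moments of a mask.

    Eigenvalues of [[mu20, mu11], [mu11, mu02]] (per-pixel 1/12 correction
    included) give axis lengths 4*sqrt(lambda); orientation follows the
    principal eigenvector; the centroid is the first moment in continuous
    coordinates (pixel centres at index + 0.5).
    """
    ys, xs = np.nonzero(np.asarray(mask, dtype=bool))
    n = xs.size
    if n < 5:
        raise ValueError("mask too small for a moment ellipse fit")
    cx = xs.mean()
    cy = ys.mean()
    dx = xs - cx
    dy = ys - cy
    mu20 = float(np.dot(dx, dx)) / n + 1.0 / 12.0
    mu02 = float(np.dot(dy, dy)) / n + 1.0 / 12.0
    mu11 = float(np.dot(dx, dy)) / n
    common = np.hypot(mu20 - mu02, 2 * mu11)
    lam_max = 0.5 * (mu20 + mu02 + common)
    lam_min = 0.5 * (mu20 + mu02 - common)
    orientation = 0.5 * np.arctan2(2 * mu11, mu20 - mu02)
    return EllipseFit(major_px=4.0 * np.sqrt(lam_max),
                      minor_px=4.0 * np.sqrt(max(lam_min, 0.0)),
                      orientation_rad=float(orientation),
                      centroid_x_px=float(cx + 0.5),
                      centroid_y_px=float(cy + 0.5))


def optical_deformability(major: float, minor: float) -> float:
    """OD = major axis / minor axis (axes sorted, so OD >= 1)."""
    lo, hi = sorted((float(major), float(minor)))
    if lo <= 0:
        raise ValueError("axes must be positive")
    return hi / lo


def calibrate_pixels(bead_mean_axis_px) -> float:
    """Pixel scale from beads: 10 um / median bead mean-axis in pixels."""
    v = np.asarray(bead_mean_axis_px, dtype=float)
    if v.size < 10:
        raise ValueError("need at least 10 bead measurements")
    return 10.0 / float(np.median(v))


def optical_diameter(major_px, minor_px, calib: OpticalCalibration):
    """Area-equivalent diameter, rescaled so the bead median reads 10 um.

    d_raw = sqrt(major * minor) * pixel_scale, then multiplied by the bead
    reference factor; the bead referencing cancels the pixel scale, making
    the result insensitive to the axis convention chosen.
    """
    if calib is None or calib.bead_axis_gm_px_median <= 0:
        raise ValueError("missing or invalid bead calibration")
    gm = np.sqrt(np.asarray(major_px, float) * np.asarray(minor_px, float))
    d_raw = gm * calib.pixel_scale_um
    factor = calib.bead_diameter_um / (calib.bead_axis_gm_px_median
                                       * calib.pixel_scale_um)
    d = d_raw * factor
    return float(d) if d.ndim == 0 else d


def measure_frame(frame: Frame, geom: ChannelGeometry,
                  acq: AcquisitionSettings,
                  params: SegmentationParams | None = None,
                  ) -> OpticalMeasurement | None:
    """Segment and measure the (largest) object of one frame.

    Returns None when no component survives the minimum-area and edge
    filters ("no cell in frame").  The lateral position ``y_um`` is the
    centroid offset from the channel midline.
    """
    img = preprocess(frame.image)
    mask, count = segment_cell(img, params)
    if mask is None:
        return None
    fit = fit_ellipse_moments(mask)
    h, w = img.shape
    scale = acq.pixel_scale_um
    return OpticalMeasurement(
        frame_index=frame.frame_index, timestamp_s=frame.timestamp_s,
        centroid_x_px=fit.centroid_x_px, centroid_y_px=fit.centroid_y_px,
        major_px=fit.major_px, minor_px=fit.minor_px,
        orientation_rad=fit.orientation_rad,
        od=optical_deformability(fit.major_px, fit.minor_px),
        y_um=(fit.centroid_y_px - h / 2) * scale,
        x_um=(fit.centroid_x_px - w / 2) * scale,
        n_objects_in_frame=count)


def measure_frames(frames, geom: ChannelGeometry, acq: AcquisitionSettings,
                   params: SegmentationParams | None = None) -> pd.DataFrame:
    """Per-frame measurement table; frames without a cell are skipped."""
    rows = []
    for frame in frames:
        m = measure_frame(frame, geom, acq, params)
        if m is not None:
            rows.append(vars(m))
    cols = ["frame_index", "timestamp_s", "centroid_x_px", "centroid_y_px",
            "major_px", "minor_px", "orientation_rad", "od", "y_um", "x_um",
            "n_objects_in_frame", "optical_diameter_um"]
    return pd.DataFrame(rows, columns=cols)
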