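"""Trace extraction from aspiration image sequences.

Implements the classical segmentation chain for pipette-entry videos:
frame differencing, thresholding, particle removal by morphological
opening, edge detection and least-squares contour (circle) fitting.  The
pipette geometry (centreline row, mouth column) is taken from the
acquisition settings — auto-detection is out of scope.

Coordinate convention: row/column with origin at the top-left, 0-based,
half-open pixel intervals; columns increase into the pipette.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from skimage import filters, measure, morphology

from .traces import (
    FLAG_INTERPOLATED,
    FLAG_LOW_CONTRAST,
    AcquisitionSettings,
    AspirationTrace,
)


class ThresholdResult(NamedTuple):
    mask: np.ndarray
    threshold: float
    degenerate: bool


@dataclass
class CircleFit:
    """Least-squares circle fit of a cell contour."""

    radius_um: float
    center_row: float
    center_col: float
    residual_um: float  # mean absolute radial residual
    frame_index: int


def threshold_mask(image: np.ndarray, threshold: float | None = None) -> ThresholdResult:
    """Binarize a grayscale frame.

    Otsu's method by default; pass ``threshold`` for a fixed value.  A
    constant image (Otsu undefined) yields an empty mask with the
    ``degenerate`` flag set.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    if threshold is None:
        if np.ptp(image) == 0:
            return ThresholdResult(np.zeros(image.shape, dtype=bool), float("nan"), True)
        threshold = float(filters.threshold_otsu(image))
    return ThresholdResult(image > threshold, float(threshold), False)


def difference_frames(stack: np.ndarray, threshold: float | str = "otsu") -> np.ndarray:
    """Change masks between consecutive frames.

    ``mask[k] = |frame[k+1] - frame[k]| > threshold``; the stack shrinks by
    one frame.  ``threshold`` is either a fixed value or ``"otsu"``
    (per-pair automatic, empty mask for static pairs).
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a stack of >= 2 equally sized frames")
    diffs = np.abs(np.diff(stack, axis=0))
    if threshold == "otsu":
        masks = np.empty(diffs.shape, dtype=bool)
        for k, d in enumerate(diffs):
            masks[k] = threshold_mask(d)[0] if np.ptp(d) > 0 else np.zeros(d.shape, bool)
        return masks
    return diffs > float(threshold)


def clean_mask(mask: np.ndarray, radius_px: int = 1, min_area: int = 4) -> np.ndarray:
    """Particle removal: morphological opening + small-component filtering.

    Opening with a disk of ``radius_px`` (no-op at radius 0), then removal
    of connected components below ``min_area`` pixels.
    """
    if radius_px < 0:
        raise ValueError(f"radius_px must be >= 0, got {radius_px}")
    mask = np.asarray(mask, dtype=bool)
    if radius_px > 0:
        mask = morphology.opening(mask, morphology.disk(radius_px))
    if min_area > 0:
        mask = morphology.remove_small_objects(mask, max_size=min_area - 1)
    return mask


def _component_outside_mouth(mask: np.ndarray, mouth: int) -> np.ndarray | None:
    """Largest connected component strictly left of the pipette mouth."""
    outside = mask.copy()
    outside[:, mouth:] = False
    labels = measure.label(outside)
    if labels.max() == 0:
        return None
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def measure_cell_radius(
    stack: np.ndarray,
    acq: AcquisitionSettings,
    *,
    threshold: float | None = None,
    residual_tol_um: float | None = None,
) -> CircleFit:
    """Cell radius from the first pre-entry frame by circle fitting.

    The cell body outside the mouth is segmented, its edge extracted at
    sub-pixel precision (iso-contour of the grayscale frame at the midpoint
    of the estimated foreground/background levels) and fitted with a
    total-least-squares circle.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError("expected a frame or stack of frames")
    _, mouth = acq.require_geometry()

    for k, frame in enumerate(stack):
        mask, thr, degenerate = threshold_mask(frame, threshold)
        if degenerate:
            continue
        comp = _component_outside_mouth(clean_mask(mask), mouth)
        if comp is None:
            continue
        # contrast-midpoint level for sub-pixel edge localization
        interior = morphology.erosion(comp, morphology.disk(2))
        if not interior.any():
            interior = comp
        bg = ~morphology.dilation(comp, morphology.disk(3))
        bg[:, mouth:] = False
        fg_level = float(np.mean(frame[interior]))
        bg_level = float(np.mean(frame[bg])) if bg.any() else 0.0
        level = 0.5 * (fg_level + bg_level)

        contours = [
            c for c in measure.find_contours(frame, level)
            if len(c) >= 8 and np.mean(c[:, 1]) < mouth
        ]
        if not contours:
            continue
        contour = max(contours, key=len)
        model = measure.CircleModel.from_estimate(contour)
        if not model:
            raise ValueError(f"circle fit failed on frame {k}")
        (cy, cx), r = model.center, model.radius
        resid = float(np.mean(np.abs(np.hypot(contour[:, 0] - cy, contour[:, 1] - cx) - r)))
        fit = CircleFit(
            radius_um=r * acq.pixel_size,
            center_row=cy,
            center_col=cx,
            residual_um=resid * acq.pixel_size,
            frame_index=k,
        )
        if residual_tol_um is not None and fit.residual_um > residual_tol_um:
            raise ValueError(
                f"circle fit residual {fit.residual_um:.3g} µm exceeds tolerance "
                f"{residual_tol_um} µm on frame {k}"
            )
        return fit
    raise ValueError(
        f"no cell body found outside the pipette mouth in any of {stack.shape[0]} "
        f"frame(s) (last checked frame {stack.shape[0] - 1})"
    )


def _leading_edge_px(
    mask: np.ndarray, axis: int, mouth: int, half_rows: int = 1
) -> float:
    """Furthest in-channel foreground column on the pipette axis, or -inf."""
    rows = slice(max(axis - half_rows, 0), axis + half_rows + 1)
    band = mask[rows, mouth:]
    cols = np.nonzero(band.any(axis=0))[0]
    if cols.size == 0:
        return -np.inf
    # contiguous run attached to the mouth; stray blobs beyond a gap ignored
    gaps = np.nonzero(np.diff(cols) > 1)[0]
    last = cols[gaps[0]] if gaps.size else cols[-1]
    return float(last)


def measure_Lp(
    stack: np.ndarray,
    acq: AcquisitionSettings,
    *,
    threshold: float | None = None,
    clean_radius_px: int = 1,
    max_failed_fraction: float = 0.2,
    cell_id: str = "cell",
    cell_radius_um: float | None = None,
) -> AspirationTrace:
    """Per-frame aspiration length from an image stack.

    For each frame the thresholded, cleaned mask is scanned along the
    pipette axis; ``Lp`` is the leading-edge column minus the mouth column
    (pixel-centre convention, clipped at 0) times the pixel size.  Frames
    with degenerate contrast are linearly interpolated from neighbours and
    flagged; a trace with more than ``max_failed_fraction`` failed frames is
    rejected.  The cell radius is measured from the first pre-entry frame
    unless supplied.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("expected an image stack (frames, rows, cols)")
    axis, mouth = acq.require_geometry()
    if acq.pixel_size * stack.shape[2] < 4 * acq.pipette_radius:
        raise ValueError("image width below 4 pipette radii; geometry implausible")

    n = stack.shape[0]
    lp = np.zeros(n)
    flags = np.zeros(n, dtype=np.uint8)
    failed = np.zeros(n, dtype=bool)
    for k, frame in enumerate(stack):
        mask, _, degenerate = threshold_mask(frame, threshold)
        if degenerate:
            failed[k] = True
            flags[k] |= FLAG_LOW_CONTRAST
            continue
        mask = clean_mask(mask, clean_radius_px)
        edge = _leading_edge_px(mask, axis, mouth)
        lp[k] = max((edge + 0.5) * acq.pixel_size, 0.0) if np.isfinite(edge) else 0.0

    if failed.mean() > max_failed_fraction:
        raise ValueError(
            f"{cell_id}: {int(failed.sum())}/{n} frames failed detection "
            f"(> {max_failed_fraction:.0%}); trace rejected"
        )
    if failed.any():
        good = np.nonzero(~failed)[0]
        if good.size == 0:
            raise ValueError(f"{cell_id}: no usable frames")
        lp[failed] = np.interp(np.nonzero(failed)[0], good, lp[good])
        flags[failed] |= FLAG_INTERPOLATED

    if cell_radius_um is None:
        cell_radius_um = measure_cell_radius(stack[:1], acq, threshold=threshold).radius_um

    times = np.arange(n) / acq.frame_rate
    return AspirationTrace(
        cell_id=cell_id,
        cell_radius=cell_radius_um,
        times=times,
        lengths=lp,
        flags=flags,
        meta={"mouth_col": mouth, "axis_row": axis},
    )
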