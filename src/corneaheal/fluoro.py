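"""Ruler-calibrated planimetry of fluorescein-stained corneal wounds.

Photographs taken under cobalt-blue light show the de-epithelialized cornea as
a bright green fluorescein pool.  A ruler photographed in the same frame gives
a per-image calibration factor (mm per pixel); the wound is segmented on a
fluorescein score F = G - (R + B)/2 and its pixel count converted to mm^2.
No curvature correction is applied to photographs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .geometry import ValidationError
from .octpipe import _CONN4, WoundMask, WoundMeasurement
from .synthetic import Photo

__all__ = [
    "CalibrationError",
    "Calibration",
    "calibrate_from_ruler",
    "segment_wound_photo",
    "photo_wound_area",
    "measure_photo_wound",
]


class CalibrationError(RuntimeError):
    """The ruler region yielded too few tick marks for a scale estimate."""


@dataclass(frozen=True)
class Calibration:
    """Per-image scale from ruler tick detection."""

    mm_per_px: float
    n_ticks_detected: int
    residual_px: float

    def __post_init__(self) -> None:
        if not self.mm_per_px > 0:
            raise ValidationError("mm_per_px must be > 0")
        if self.n_ticks_detected < 3:
            raise ValidationError("calibration needs >= 3 detected ticks")


def calibrate_from_ruler(
    photo: Photo,
    ruler_region: tuple[int, int, int, int] | None = None,
    tick_spacing_mm: float = 1.0,
) -> Calibration:
    """Estimate mm-per-pixel from the ruler photographed with the eye.

    ``ruler_region`` is (row0, row1, col0, col1); when omitted, the ground-truth
    region recorded by the synthetic generator is used.  The region is averaged
    into a 1-D intensity profile, dark tick marks are located by peak
    detection, and the scale is ``tick_spacing_mm`` divided by the
    least-squares slope of tick position against tick index (robust to the
    +/- 1 px rounding of individual gaps); the MAD of inter-tick distances is
    reported as the residual, and grossly aperiodic peaks raise
    :class:`CalibrationError`.
    """
    if tick_spacing_mm <= 0:
        raise ValidationError("tick_spacing_mm must be > 0")
    if ruler_region is None:
        ruler_region = photo.metadata.get("ruler_region")
        if ruler_region is None:
            raise CalibrationError("no ruler_region given and none in photo metadata")
    r0, r1, c0, c1 = (int(v) for v in ruler_region)
    h, w = photo.rgb.shape[:2]
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValidationError(f"ruler_region {ruler_region} outside the {h}x{w} image")

    gray = photo.rgb[r0:r1, c0:c1].astype(float).mean(axis=2)
    profile = gray.mean(axis=0)
    inverted = profile.max() - profile  # ticks are dark
    span = float(np.ptp(inverted))
    if span <= 0:
        raise CalibrationError("ruler region has no intensity structure")
    peaks, _ = find_peaks(inverted, prominence=0.3 * span, distance=3)
    if len(peaks) < 3:
        raise CalibrationError(f"only {len(peaks)} tick marks found (need >= 3)")
    gaps = np.diff(peaks).astype(float)
    med = float(np.median(gaps))
    residual = float(np.median(np.abs(gaps - med)))
    worst = float(np.max(np.abs(gaps - med)))
    if worst > max(0.25 * med, 1.5):
        raise CalibrationError(
            f"detected peaks are not periodic (worst gap deviates {worst:.1f} px "
            f"from the {med:.1f} px spacing)"
        )
    # least-squares slope of position vs tick index: unbiased by the +/- 1 px
    # rounding that a median of integer gaps inherits
    spacing = float(np.polyfit(np.arange(len(peaks)), peaks, 1)[0])
    return Calibration(
        mm_per_px=tick_spacing_mm / spacing, n_ticks_detected=int(len(peaks)), residual_px=residual
    )


def fluorescein_score(rgb: np.ndarray) -> np.ndarray:
    """Per-pixel fluorescein score F = G - (R + B)/2 on channels scaled to [0, 1]."""
    x = rgb.astype(float) / 255.0
    return x[..., 1] - 0.5 * (x[..., 0] + x[..., 2])


def segment_wound_photo(
    photo: Photo,
    roi: np.ndarray | None = None,
    min_area_px: int = 64,
    min_score_range: float = 0.08,
) -> WoundMask:
    """Segment the fluorescein pool on a cobalt-blue photograph.

    Otsu threshold on the fluorescein score (within ``roi``; the ruler band is
    excluded automatically when the photo metadata locates it), morphological
    opening, largest 4-connected component, hole fill.  Returns an empty mask
    with the ``empty_wound`` flag for photos with no green excess (healed
    cornea) or when the component is below ``min_area_px``.
    """
    rgb = photo.rgb
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValidationError("photo must be RGB")
    F = fluorescein_score(rgb)
    if not np.all(np.isfinite(F)):
        raise ValidationError("photo contains non-finite values")

    if roi is None:
        roi = np.ones(F.shape, bool)
        rr = photo.metadata.get("ruler_region")
        if rr is not None:
            r0, r1, c0, c1 = (int(v) for v in rr)
            roi[r0:r1, c0:c1] = False
    else:
        roi = roi.astype(bool)

    empty = WoundMask(np.zeros(F.shape, bool), None, empty_wound=True, meta={"reason": ""})
    vals = F[roi]
    if vals.size == 0 or float(np.ptp(vals)) < min_score_range:
        empty.meta["reason"] = "no fluorescein excess"
        return empty
    t = threshold_otsu(vals)
    fg = (F > t) & roi
    fg = ndimage.binary_opening(fg, structure=disk(3))
    if not fg.any():
        empty.meta["reason"] = "opening removed all foreground"
        return empty
    labels, n = ndimage.label(fg, structure=_CONN4)
    largest = np.argmax(ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))) + 1
    fg = ndimage.binary_fill_holes(labels == largest)
    if int(fg.sum()) < min_area_px:
        empty.meta.update(reason=f"component {int(fg.sum())} px < min {min_area_px}", otsu=float(t))
        return empty
    return WoundMask(mask=fg, pitch=None, empty_wound=False, meta={"otsu": float(t)})


def photo_wound_area(mask: WoundMask, cal: Calibration) -> WoundMeasurement:
    """Convert a photo wound mask to mm^2 with the per-image calibration.

    ``area = N_fg * mm_per_px^2``; method label ``"FLUO"``.  Photographic areas
    carry no curvature correction.
    """
    area = mask.n_foreground * cal.mm_per_px**2
    eq_diam = 2.0 * np.sqrt(area / np.pi)
    return WoundMeasurement(
        method="FLUO",
        area_mm2=float(area),
        equivalent_diameter_mm=float(eq_diam),
        empty_wound=mask.empty_wound,
        diagnostics={
            "mm_per_px": cal.mm_per_px,
            "n_ticks": cal.n_ticks_detected,
            "residual_px": cal.residual_px,
            "n_foreground_px": mask.n_foreground,
        },
    )


def measure_photo_wound(
    photo: Photo,
    ruler_region: tuple[int, int, int, int] | None = None,
    tick_spacing_mm: float = 1.0,
    roi: np.ndarray | None = None,
) -> WoundMeasurement:
    """End-to-end photo planimetry: calibrate from the ruler, segment, convert to mm^2."""
    cal = calibrate_from_ruler(photo, ruler_region, tick_spacing_mm)
    mask = segment_wound_photo(photo, roi=roi)
    return photo_wound_area(mask, cal)
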