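"""SDS-PAGE lane densitometry.

Quantifies protein bands from a 1-D intensity profile along a gel lane's
migration axis: a morphological-opening baseline is removed, bands are
integrated over fixed index windows, normalised to total lane protein, and
ratios between bands (e.g. myosin heavy chain ~220 kDa over actin ~42 kDa)
are formed.  Band windows can be located from a molecular-weight ladder via a
log-linear migration fit.  All intensities are in arbitrary units; only
fractions and ratios are meaningful, as in stained-gel practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import DensitometryError, ValidationError


@dataclass(frozen=True)
class LaneProfile:
    """1-D intensity profile along a gel lane's migration axis."""

    intensities: np.ndarray
    lane_id: str = ""

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 1 or arr.size < 16:
            raise ValidationError("lane profile needs >= 16 samples")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("lane profile contains non-finite values")
        object.__setattr__(self, "intensities", arr)

    def __len__(self) -> int:
        return self.intensities.size


@dataclass(frozen=True)
class BandWindow:
    """Half-open sample-index window [start_idx, end_idx) holding one band."""

    name: str
    start_idx: int
    end_idx: int

    def __post_init__(self):
        if not (0 <= self.start_idx < self.end_idx):
            raise ValidationError(f"bad band window {self.name!r}: "
                                  f"[{self.start_idx}, {self.end_idx})")


@dataclass(frozen=True)
class BandQuant:
    """Integrated band quantity, lane total, and the band's lane fraction.

    ``fraction_of_lane`` is NaN (and ``lane_empty`` True) when the lane total
    is zero.
    """

    band_total: float
    lane_total: float
    fraction_of_lane: float
    lane_empty: bool = False
    name: str = ""


def subtract_background(profile: LaneProfile, radius: int) -> LaneProfile:
    """Remove a rolling-minimum-then-maximum (morphological opening) baseline.

    ``radius`` is the half-width in samples of the structuring element; it
    should comfortably exceed the band width so bands are not absorbed into
    the baseline.  On noisy lanes a raw opening rides the noise *minima* and
    so sits systematically below the true baseline, which would inflate every
    integral downstream; the opening is therefore recentred by the median of
    the raw residual before subtraction.  Residual negative values are
    clipped to zero.
    """
    if radius < 1:
        raise ValidationError("radius must be >= 1")
    if radius >= len(profile):
        raise ValidationError("radius must be smaller than the profile length")
    y = profile.intensities
    baseline = ndimage.grey_opening(y, size=2 * radius + 1, mode="nearest")
    baseline = baseline + np.median(y - baseline)
    return LaneProfile(np.clip(y - baseline, 0.0, None), profile.lane_id)


def quantify_band(profile: LaneProfile, window: BandWindow) -> BandQuant:
    """Integrate one band window and the whole (background-subtracted) lane."""
    y = profile.intensities
    if window.end_idx > y.size:
        raise DensitometryError(
            f"window {window.name!r} [{window.start_idx}, {window.end_idx}) "
            f"exceeds lane length {y.size}"
        )
    band_total = float(y[window.start_idx : window.end_idx].sum())
    lane_total = float(y.sum())
    if lane_total == 0:
        return BandQuant(band_total, 0.0, float("nan"), lane_empty=True,
                         name=window.name)
    return BandQuant(band_total, lane_total, band_total / lane_total,
                     name=window.name)


def band_ratio(a: BandQuant, b: BandQuant) -> float:
    """Ratio of two integrated band quantities (e.g. MyHC / actin)."""
    if not (b.band_total > 0):
        raise DensitometryError(
            f"denominator band {b.name!r} has non-positive total "
            f"({b.band_total}); ratio undefined"
        )
    return a.band_total / b.band_total


@dataclass(frozen=True)
class MigrationCalibration:
    """Log-linear fit of molecular weight to migration position.

    log10(MW) = intercept + slope * position.  Queries outside the fitted
    ladder range are flagged as extrapolations.
    """

    slope: float
    intercept: float
    position_range: tuple[float, float]
    mw_range_kda: tuple[float, float]

    def position_for_mw(self, mw_kda: float) -> tuple[float, bool]:
        """Predicted migration position for a molecular weight, with an
        extrapolation flag."""
        if mw_kda <= 0:
            raise ValidationError("molecular weight must be positive")
        pos = (math.log10(mw_kda) - self.intercept) / self.slope
        lo, hi = self.mw_range_kda
        extrapolated = not (lo <= mw_kda <= hi)
        return pos, extrapolated

    def mw_at(self, position: float) -> float:
        return 10 ** (self.intercept + self.slope * position)


def calibrate_migration(
    ladder: Sequence[tuple[float, float]]
) -> MigrationCalibration:
    """Fit migration position against log10 molecular weight from a ladder.

    ``ladder`` is a sequence of (sample position, molecular weight in kDa)
    pairs, at least three, with distinct positions; molecular weight must be
    strictly monotone in position (heavier proteins migrate less far).
    """
    if len(ladder) < 3:
        raise ValidationError("ladder needs >= 3 points")
    pos = np.asarray([p for p, _ in ladder], dtype=float)
    mw = np.asarray([m for _, m in ladder], dtype=float)
    if np.any(mw <= 0):
        raise ValidationError("ladder molecular weights must be positive")
    if np.unique(pos).size != pos.size:
        raise ValidationError("ladder positions must be distinct")
    order = np.argsort(pos)
    d = np.diff(mw[order])
    if not (np.all(d > 0) or np.all(d < 0)):
        raise DensitometryError("ladder is not monotone in migration position")
    slope, intercept = np.polyfit(pos, np.log10(mw), 1)
    return MigrationCalibration(
        slope=float(slope),
        intercept=float(intercept),
        position_range=(float(pos.min()), float(pos.max())),
        mw_range_kda=(float(mw.min()), float(mw.max())),
    )
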