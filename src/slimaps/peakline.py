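"""Per-profile peak analysis for Scattered Light Imaging (SLI).

An SLI measurement illuminates a thin brain section obliquely from a
sequence of azimuthal positions and records the normally transmitted light.
Each image pixel then carries an *azimuthal intensity profile* ``I(phi)``:
intensity as a function of the illumination azimuth ``phi`` (0 deg at twelve
o'clock, increasing clockwise).  In-plane nerve fibers scatter light
predominantly perpendicular to their axis, so a fiber bundle with in-plane
direction ``phi_f`` produces a pair of peaks near ``phi_f +/- 90`` deg;
crossing bundles superimpose their peak pairs.

This module implements the per-profile primitives on the 360-deg periodic
signal:

* mean normalization of a profile,
* detection of circular local maxima (with plateau handling and
  wrap-around),
* peak prominence relative to the total signal amplitude ``Imax - Imin``,
* full width at the height ``peak - prominence/2`` via linear
  interpolation,
* sub-sample peak-position correction: the raw sample position is replaced
  by the circular midpoint of the two flank crossings of a cut placed a
  small fraction (default 6% of the amplitude) below the peak tip, which
  reduces the discretization error of a 15-deg sampling grid from a uniform
  +/- 7.5 deg to a roughly Gaussian +/- 2.4 deg.

All operations are invariant under positive affine rescaling of the
intensities and equivariant under circular rotation of the profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DegenerateProfileError",
    "AngularProfile",
    "Peak",
    "FLAT_AMPLITUDE_FRACTION",
    "DEFAULT_PROMINENCE_THRESHOLD",
    "DEFAULT_TIP_FRACTION",
    "is_flat",
    "normalize_profile",
    "detect_peaks",
    "compute_prominences",
    "filter_prominent",
    "compute_widths",
    "correct_peak_positions",
    "analyze_profile",
]

#: Profiles whose amplitude is below this fraction of their mean intensity
#: are classified as flat: they carry no usable orientation signal and yield
#: no peaks and no directions.
FLAT_AMPLITUDE_FRACTION = 1e-9

#: Default relative-prominence threshold separating signal peaks from noise
#: wiggles (fraction of the total signal amplitude Imax - Imin).
DEFAULT_PROMINENCE_THRESHOLD = 0.08

#: Default tip-cut depth for the sub-sample position correction (fraction of
#: the total signal amplitude below the peak top).
DEFAULT_TIP_FRACTION = 0.06


class DegenerateProfileError(ValueError):
    """Raised when a profile has no usable signal (zero mean or amplitude)."""


@dataclass(frozen=True)
class AngularProfile:
    """Intensity versus illumination azimuth for one pixel.

    Parameters
    ----------
    values
        Intensity per azimuth sample, arbitrary nonnegative units.
    step_deg
        Angular step between consecutive samples in degrees.  The samples
        must tile the full circle: ``len(values) * step_deg == 360``.
    start_deg
        Azimuth of sample 0 in degrees (0 = twelve o'clock).
    """

    values: np.ndarray
    step_deg: float
    start_deg: float = 0.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 6:
            raise ValueError(f"profile needs >= 6 samples, got shape {vals.shape}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("profile contains non-finite values")
        if self.step_deg <= 0:
            raise ValueError("step_deg must be positive")
        if abs(vals.size * self.step_deg - 360.0) > 1e-9:
            raise ValueError(
                f"{vals.size} samples at {self.step_deg} deg do not cover 360 deg"
            )

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def angles_deg(self) -> np.ndarray:
        """Azimuth of each sample in degrees."""
        return self.start_deg + self.step_deg * np.arange(self.n)

    @property
    def amplitude(self) -> float:
        """Total signal amplitude Imax - Imin."""
        return float(self.values.max() - self.values.min())


@dataclass
class Peak:
    """One detected peak of an angular profile.

    ``index`` is the raw sample index of the local maximum; the remaining
    fields are filled in by :func:`compute_prominences`,
    :func:`compute_widths` and :func:`correct_peak_positions`.
    ``prominence`` is in profile intensity units; ``prominence_rel`` is the
    same divided by the profile amplitude.
    """

    index: int
    position_deg: float | None = None
    prominence: float | None = field(default=None, repr=False)
    prominence_rel: float | None = None
    width_deg: float | None = None


def is_flat(p: AngularProfile) -> bool:
    """True if the profile carries no usable modulation.

    A profile is flat when its amplitude is below
    ``FLAT_AMPLITUDE_FRACTION`` of its mean intensity, or when its mean is
    not positive.
    """
    m = float(np.mean(p.values))
    if m <= 0:
        return True
    return p.amplitude < FLAT_AMPLITUDE_FRACTION * m


def normalize_profile(p: AngularProfile) -> AngularProfile:
    """Divide the profile by its mean intensity over all azimuths.

    The normalized profile has mean exactly 1, making profiles from pixels
    with different transmittance comparable.

    Raises
    ------
    DegenerateProfileError
        If the mean intensity is not positive (e.g. an all-zero profile).
    """
    m = float(np.mean(p.values))
    if m <= 0:
        raise DegenerateProfileError("degenerate profile: mean intensity <= 0")
    return replace(p, values=p.values / m)


def detect_peaks(p: AngularProfile) -> list[Peak]:
    """Find circular local maxima of the profile.

    A sample (or plateau of equal samples) is a peak when it exceeds both
    of its circular neighbors; the 360-deg periodicity is honored, so maxima
    at index 0 or the last index are detected.  A plateau yields a single
    peak at its center sample, rounding to the lower index for plateaus of
    even length.  Constant and flat profiles yield no peaks.
    """
    v = p.values
    n = v.size
    if is_flat(p) or np.all(v == v[0]):
        return []
    # Start the circular run decomposition at a value change so no run is
    # split across the wrap point.
    start = next(i for i in range(n) if v[i] != v[i - 1])
    peaks: list[Peak] = []
    i = start
    covered = 0
    while covered < n:
        length = 1
        while v[(i + length) % n] == v[i]:
            length += 1
        before = v[(i - 1) % n]
        after = v[(i + length) % n]
        if v[i] > before and v[i] > after:
            peaks.append(Peak(index=(i + (length - 1) // 2) % n))
        covered += length
        i = (i + length) % n
    peaks.sort(key=lambda pk: pk.index)
    return peaks


def compute_prominences(p: AngularProfile, peaks: list[Peak]) -> list[Peak]:
    """Attach prominence and relative prominence to each peak.

    The prominence is the vertical distance between the top of the peak and
    the higher of the two flanking minima, where each flanking minimum is
    the lowest value encountered while walking circularly from the peak to
    the next strictly higher sample (or around the full circle if none
    exists).  The relative prominence divides by the profile amplitude
    ``Imax - Imin``.
    """
    v = p.values
    n = v.size
    amp = p.amplitude
    if peaks and amp <= 0:
        raise DegenerateProfileError("degenerate profile: zero amplitude")
    for pk in peaks:
        i = pk.index
        top = v[i]
        side_minima = []
        for direction in (-1, 1):
            lowest = top
            for step in range(1, n):
                val = v[(i + direction * step) % n]
                if val > top:
                    break
                if val < lowest:
                    lowest = val
            side_minima.append(lowest)
        pk.prominence = float(top - max(side_minima))
        pk.prominence_rel = pk.prominence / amp
    return peaks


def filter_prominent(
    peaks: list[Peak], threshold_rel: float = DEFAULT_PROMINENCE_THRESHOLD
) -> list[Peak]:
    """Keep peaks whose relative prominence reaches ``threshold_rel``.

    The default 8% threshold discards small irregularities of the profile
    that would otherwise be misread as fiber signals.
    """
    if not 0.0 <= threshold_rel <= 1.0:
        raise ValueError(f"threshold_rel must be in [0, 1], got {threshold_rel}")
    for pk in peaks:
        if pk.prominence_rel is None:
            raise ValueError("prominences must be computed before filtering")
    return [pk for pk in peaks if pk.prominence_rel >= threshold_rel]


def _flank_crossing(
    v: np.ndarray, i: int, height: float, direction: int
) -> float | None:
    """Offset (in samples, signed) from ``i`` to the flank crossing of ``height``.

    Walks circularly from sample ``i`` in ``direction`` (+1 right, -1 left)
    until the signal drops below ``height`` and linearly interpolates the
    crossing.  Returns None if the walk starts rising again before crossing
    (the region merges with a neighboring peak) or never crosses.
    """
    n = v.size
    prev = v[i]
    for step in range(1, n + 1):
        cur = v[(i + direction * step) % n]
        if cur < height:
            t = (prev - height) / (prev - cur)
            return direction * (step - 1 + t)
        if cur > prev:
            return None
        prev = cur
    return None


def compute_widths(p: AngularProfile, peaks: list[Peak]) -> list[Peak]:
    """Attach the full width at half-prominence height to each peak.

    The evaluation height is ``peak value - prominence / 2``; the left and
    right crossings of this height are located by circular linear
    interpolation between samples and the width is their circular distance
    in degrees.
    """
    v = p.values
    for pk in peaks:
        if pk.prominence is None:
            raise ValueError("prominences must be computed before widths")
        height = v[pk.index] - pk.prominence / 2.0
        left = _flank_crossing(v, pk.index, height, -1)
        right = _flank_crossing(v, pk.index, height, +1)
        if left is None or right is None:
            # Height lies below a flanking valley; should not occur for a
            # positive prominence, but guard with the widest sane answer.
            pk.width_deg = float(p.step_deg * v.size)
        else:
            pk.width_deg = float((right - left) * p.step_deg)
    return peaks


def correct_peak_positions(
    p: AngularProfile,
    peaks: list[Peak],
    tip_fraction: float = DEFAULT_TIP_FRACTION,
) -> list[Peak]:
    """Attach sub-sample corrected positions via the tip geometric center.

    A cut is placed ``tip_fraction`` of the total signal amplitude below the
    peak top; the two crossings of the cut on the peak's own flanks are
    found by circular linear interpolation, and the corrected position is
    their circular midpoint.  If a flank starts rising again before
    reaching the cut (the tip merges with a neighboring peak's tip), the
    correction falls back to the raw sample position.

    On a 15-deg grid this reduces the position error of smooth peaks from a
    uniform +/- 7.5 deg to a roughly Gaussian spread of about +/- 2.4 deg.
    """
    if not 0.0 <= tip_fraction <= 1.0:
        raise ValueError(f"tip_fraction must be in [0, 1], got {tip_fraction}")
    v = p.values
    amp = p.amplitude
    if peaks and amp <= 0:
        raise DegenerateProfileError("degenerate profile: zero amplitude")
    for pk in peaks:
        cut = v[pk.index] - tip_fraction * amp
        left = _flank_crossing(v, pk.index, cut, -1)
        right = _flank_crossing(v, pk.index, cut, +1)
        if left is None or right is None:
            offset = 0.0
        else:
            offset = (left + right) / 2.0
        pk.position_deg = float(
            (p.start_deg + (pk.index + offset) * p.step_deg) % 360.0
        )
    return peaks


def analyze_profile(
    p: AngularProfile,
    prominence_threshold: float = DEFAULT_PROMINENCE_THRESHOLD,
    tip_fraction: float = DEFAULT_TIP_FRACTION,
) -> tuple[list[Peak], list[Peak]]:
    """Run the full per-profile chain on a raw profile.

    Normalizes, detects peaks, computes prominences and widths, corrects
    positions, and filters by relative prominence.  Returns
    ``(all_peaks, prominent_peaks)``; the prominent list shares the Peak
    objects of the full list.
    """
    if is_flat(p):
        return [], []
    pn = normalize_profile(p)
    peaks = detect_peaks(pn)
    compute_prominences(pn, peaks)
    compute_widths(pn, peaks)
    correct_peak_positions(pn, peaks, tip_fraction=tip_fraction)
    prominent = filter_prominent(peaks, prominence_threshold)
    return peaks, prominent
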