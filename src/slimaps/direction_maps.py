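"""From per-pixel peak sets to fiber directions and whole-image parameter maps.

Fiber directions are *axial* quantities: a direction and its opposite
describe the same fiber, so all directions live in [0, 180) deg.  The rules
mapping prominent peaks to directions are:

* 1 peak  -> the peak position itself (mod 180); typical of steeply
  inclined fibers whose peak pair has merged.
* 2 peaks -> the circular midpoint of the pair (mod 180); in-plane fibers
  give two peaks roughly 180 deg apart at ``phi_f +/- 90``.
* 4 or 6 peaks -> the peaks are paired by sorted order (i with i + n/2);
  if every pair is 180 +/- 35 deg apart, each pair's circular midpoint
  (mod 180) is one crossing fiber direction; otherwise no direction is
  reported.
* any other count -> no direction.

``build_parameter_maps`` runs the full per-pixel chain over a stack and
assembles nine maps: average intensity, peak counts (all / prominent),
average prominence and width of the prominent peaks, the two-peak distance,
and up to three direction maps.  ``median_direction_filter`` smooths a
direction map with an axial 3x3 median, which fills undefined pixels from
their neighborhood without mixing the distinct directions of crossing
bundles the way averaging would.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .peakline import (
    DEFAULT_PROMINENCE_THRESHOLD,
    DEFAULT_TIP_FRACTION,
    AngularProfile,
    analyze_profile,
)
from .stack_io import DIRECTION_SENTINEL, MapImage, SLIStack

__all__ = [
    "DEFAULT_PAIR_TOLERANCE_DEG",
    "DirectionSet",
    "ParameterMapSet",
    "axial_distance",
    "pair_peaks",
    "directions_from_peaks",
    "peak_distance",
    "build_parameter_maps",
    "median_direction_filter",
    "sample_vector_overlay",
]

#: Accepted deviation of a peak pair's separation from 180 deg.  Slightly
#: inclined fibers shrink the separation of their peak pair, so a band of
#: +/- 35 deg around 180 deg is accepted when pairing 4 or 6 peaks.
DEFAULT_PAIR_TOLERANCE_DEG = 35.0

MAX_DIRECTIONS = 3


@dataclass(frozen=True)
class DirectionSet:
    """Up to three axial fiber directions for one pixel, sorted ascending."""

    directions_deg: tuple[float, ...]
    n_used_peaks: int

    def __post_init__(self) -> None:
        if len(self.directions_deg) > MAX_DIRECTIONS:
            raise ValueError("at most 3 directions per pixel")
        for d in self.directions_deg:
            if not 0.0 <= d < 180.0:
                raise ValueError(f"direction {d} outside [0, 180)")


@dataclass
class ParameterMapSet:
    """The named 2D maps produced from one stack (shared spatial shape)."""

    avg: MapImage
    peaks_all: MapImage
    peaks_prominent: MapImage
    prominence_avg: MapImage
    width_avg: MapImage
    distance: MapImage
    dir_1: MapImage
    dir_2: MapImage
    dir_3: MapImage

    def as_dict(self) -> dict[str, MapImage]:
        return {
            "avg": self.avg,
            "peaks_all": self.peaks_all,
            "peaks_prominent": self.peaks_prominent,
            "prominence_avg": self.prominence_avg,
            "width_avg": self.width_avg,
            "distance": self.distance,
            "dir_1": self.dir_1,
            "dir_2": self.dir_2,
            "dir_3": self.dir_3,
        }


def axial_distance(a: float, b: float) -> float:
    """Distance between two axial angles: min(|a-b|, 180-|a-b|) after mod 180."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def _circular_midpoint(p1: float, p2: float) -> float:
    """Midpoint of the arc from p1 to p2 (walking in increasing azimuth)."""
    return (p1 + ((p2 - p1) % 360.0) / 2.0) % 360.0


def pair_peaks(
    positions_deg: list[float],
    tolerance_deg: float = DEFAULT_PAIR_TOLERANCE_DEG,
) -> list[tuple[int, int]] | None:
    """Pair 4 or 6 sorted peak positions into opposite-peak pairs.

    Peaks are paired by sorted order: index ``i`` with ``i + n/2``.  The
    pairing is accepted only if *every* pair's circular separation is within
    ``tolerance_deg`` of 180 deg; otherwise None is returned (all or
    nothing — one bad pair invalidates the crossing interpretation).
    """
    n = len(positions_deg)
    if n not in (4, 6):
        raise ValueError(f"pairing undefined for {n} peaks (need 4 or 6)")
    half = n // 2
    pairs = [(i, i + half) for i in range(half)]
    for i, j in pairs:
        sep = (positions_deg[j] - positions_deg[i]) % 360.0
        if abs(sep - 180.0) > tolerance_deg:
            return None
    return pairs


def directions_from_peaks(
    positions_deg: list[float],
    pair_tolerance_deg: float = DEFAULT_PAIR_TOLERANCE_DEG,
) -> DirectionSet:
    """Apply the peak-count rules to corrected peak positions.

    See the module docstring for the rules.  Results are sorted ascending;
    an empty set is returned for 0, 3, 5, or more than 6 peaks, and for 4/6
    peaks whose pairing fails the 180 +/- tolerance test.
    """
    pos = sorted(p % 360.0 for p in positions_deg)
    k = len(pos)
    dirs: list[float]
    if k == 1:
        dirs = [pos[0] % 180.0]
    elif k == 2:
        dirs = [_circular_midpoint(pos[0], pos[1]) % 180.0]
    elif k in (4, 6):
        pairs = pair_peaks(pos, pair_tolerance_deg)
        if pairs is None:
            dirs = []
        else:
            dirs = [_circular_midpoint(pos[i], pos[j]) % 180.0 for i, j in pairs]
    else:
        dirs = []
    return DirectionSet(
        directions_deg=tuple(sorted(dirs)),
        n_used_peaks=k if dirs else 0,
    )


def peak_distance(positions_deg: list[float]) -> float:
    """Separation of two prominent peaks in degrees.

    Exactly two peaks give their circular separation folded to (0, 180];
    a single peak gives 0 (the merged-pair signature of steep fibers); any
    other count gives NaN (the quantity is only defined for up to one peak
    pair).
    """
    k = len(positions_deg)
    if k == 1:
        return 0.0
    if k == 2:
        s = (positions_deg[1] - positions_deg[0]) % 360.0
        return min(s, 360.0 - s)
    return float("nan")


def build_parameter_maps(
    stack: SLIStack,
    prominence_threshold: float = DEFAULT_PROMINENCE_THRESHOLD,
    tip_fraction: float = DEFAULT_TIP_FRACTION,
    pair_tolerance_deg: float = DEFAULT_PAIR_TOLERANCE_DEG,
) -> ParameterMapSet:
    """Run the per-pixel analysis over a whole stack.

    Per pixel: normalize the profile, detect peaks, compute prominences,
    widths and corrected positions, filter by prominence, then derive the
    directions and the peak distance.  The ``avg`` map is the mean of the
    raw (non-normalized) intensities.  Prominence and width averages are
    taken over prominent peaks only (NaN where there are none).  Flat
    pixels report zero peaks and sentinels everywhere except ``avg``.
    """
    rows, cols = stack.shape_spatial
    step = stack.meta.step_deg
    start = stack.meta.start_deg

    avg = np.empty((rows, cols), dtype=np.float32)
    peaks_all = np.zeros((rows, cols), dtype=np.float32)
    peaks_prom = np.zeros((rows, cols), dtype=np.float32)
    prom_avg = np.full((rows, cols), np.nan, dtype=np.float32)
    width_avg = np.full((rows, cols), np.nan, dtype=np.float32)
    distance = np.full((rows, cols), np.nan, dtype=np.float32)
    dirs = np.full((3, rows, cols), DIRECTION_SENTINEL, dtype=np.float32)

    # Identical profiles are common (synthetic phantoms, uniform tissue);
    # cache per unique profile to avoid redundant work.
    cache: dict[bytes, tuple] = {}
    for r in range(rows):
        for c in range(cols):
            raw = stack.data[r, c, :]
            avg[r, c] = raw.mean()
            key = raw.tobytes()
            if key in cache:
                res = cache[key]
            else:
                profile = AngularProfile(raw, step_deg=step, start_deg=start)
                all_pk, prom_pk = analyze_profile(
                    profile,
                    prominence_threshold=prominence_threshold,
                    tip_fraction=tip_fraction,
                )
                positions = [pk.position_deg for pk in prom_pk]
                dset = directions_from_peaks(positions, pair_tolerance_deg)
                res = (
                    len(all_pk),
                    len(prom_pk),
                    float(np.mean([pk.prominence_rel for pk in prom_pk]))
                    if prom_pk else float("nan"),
                    float(np.mean([pk.width_deg for pk in prom_pk]))
                    if prom_pk else float("nan"),
                    peak_distance(positions),
                    dset.directions_deg,
                )
                cache[key] = res
            n_all, n_prom, p_avg, w_avg, dist, ds = res
            peaks_all[r, c] = n_all
            peaks_prom[r, c] = n_prom
            prom_avg[r, c] = p_avg
            width_avg[r, c] = w_avg
            distance[r, c] = dist
            for k, d in enumerate(ds):
                dirs[k, r, c] = d

    nan = float("nan")
    return ParameterMapSet(
        avg=MapImage(avg, "avg", nan),
        peaks_all=MapImage(peaks_all, "peaks_all", nan),
        peaks_prominent=MapImage(peaks_prom, "peaks_prominent", nan),
        prominence_avg=MapImage(prom_avg, "prominence_avg", nan),
        width_avg=MapImage(width_avg, "width_avg", nan),
        distance=MapImage(distance, "distance", nan),
        dir_1=MapImage(dirs[0], "dir_1", DIRECTION_SENTINEL),
        dir_2=MapImage(dirs[1], "dir_2", DIRECTION_SENTINEL),
        dir_3=MapImage(dirs[2], "dir_3", DIRECTION_SENTINEL),
    )


def axial_median(values: list[float]) -> float:
    """Median of axial angles: the value minimizing the summed axial distance.

    Restricted to the given values (so the result is always one of them);
    ties resolve to the smaller angle.
    """
    if not values:
        raise ValueError("axial_median of empty list")
    best = None
    best_cost = math.inf
    for cand in sorted(values):
        cost = sum(axial_distance(cand, v) for v in values)
        if cost < best_cost - 1e-12:
            best, best_cost = cand, cost
    return float(best)


def median_direction_filter(dir_map: MapImage, window: int = 3) -> MapImage:
    """Axial median filter of a direction map.

    Each pixel is replaced by the axial median of the defined directions in
    its ``window x window`` neighborhood (clipped at the borders).  Pixels
    whose whole neighborhood is undefined keep the sentinel.  This both
    denoises and fills isolated undefined pixels with the dominant local
    direction.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    half = window // 2
    data = dir_map.data
    rows, cols = data.shape
    sentinel = dir_map.undefined_sentinel
    out = np.full_like(data, sentinel)
    for r in range(rows):
        for c in range(cols):
            block = data[
                max(0, r - half): r + half + 1,
                max(0, c - half): c + half + 1,
            ]
            vals = block[block != sentinel]
            if vals.size:
                out[r, c] = axial_median(list(vals))
    return MapImage(out, dir_map.name, sentinel)


def sample_vector_overlay(
    dir_maps: "ParameterMapSet | list[MapImage]",
    stride: int = 1,
    background: MapImage | None = None,
) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Line segments visualizing the fiber directions of every stride-th pixel.

    Returns ``((x0, y0), (x1, y1))`` endpoint pairs in image coordinates
    (x = column, y = row, y growing downward).  Each defined direction of a
    sampled pixel yields one unit-length segment centered on the pixel; the
    axial angle follows the azimuth convention (0 deg points up / twelve
    o'clock, increasing clockwise).  Undefined pixels yield no segments.
    ``background`` is accepted for callers that render the segments on top
    of a map; it does not affect the geometry.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if isinstance(dir_maps, ParameterMapSet):
        maps = [dir_maps.dir_1, dir_maps.dir_2, dir_maps.dir_3]
    else:
        maps = list(dir_maps)
    segments = []
    rows, cols = maps[0].data.shape
    for r in range(0, rows, stride):
        for c in range(0, cols, stride):
            for m in maps:
                val = float(m.data[r, c])
                if val == m.undefined_sentinel:
                    continue
                phi = math.radians(val)
                dx, dy = math.sin(phi) / 2.0, -math.cos(phi) / 2.0
                segments.append(((c - dx, r - dy), (c + dx, r + dy)))
    return segments
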