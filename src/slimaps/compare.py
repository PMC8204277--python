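"""Cross-technique comparison utilities.

SLI fiber directions can be validated against two independent references:

* **Scatterometry**: a focused laser produces a full scattering pattern at
  selected tissue spots; integrating the pattern azimuthally yields a
  finely sampled (1 deg) line profile whose peaks mark the same scattering
  lobes an SLI profile samples coarsely.  :func:`line_profile_from_pattern`
  turns a simulated or measured pattern into such a profile (Gaussian blur
  matching the finite illumination aperture, then sampling along the
  illumination polar circle), :func:`normalize_minmean` puts both profiles
  on a common scale, and :func:`profile_difference_sum` /
  :func:`match_peak_sets` quantify their agreement.

* **3D polarized light imaging (3D-PLI)**: provides a reference in-plane
  direction map and a retardation map.  :func:`direction_difference_map`
  gives the per-pixel axial direction difference, and :func:`binned_std`
  summarizes its spread as a function of retardation.  Retardation itself
  falls with fiber inclination alpha as
  ``|sin(arcsin(ret_max) * cos^2 alpha)|``
  (:func:`retardation_from_inclination`), which is what links the
  retardation axis of such plots to inclination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import linear_sum_assignment

from .peakline import AngularProfile, DegenerateProfileError
from .stack_io import MapImage

__all__ = [
    "ScatteringPattern",
    "ComparisonRecord",
    "normalize_minmean",
    "profile_difference_sum",
    "match_peak_sets",
    "compare_profiles",
    "line_profile_from_pattern",
    "direction_difference_map",
    "binned_std",
    "retardation_from_inclination",
]

GAUSSIAN_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class ScatteringPattern:
    """A scattering pattern on an angular grid.

    ``values`` has axes (polar theta, azimuth psi): rows run from theta = 0
    outward in steps of ``theta_res_deg``, columns cover the full azimuth
    circle in steps of ``psi_res_deg``.
    """

    values: np.ndarray
    theta_res_deg: float
    psi_res_deg: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", arr)
        if arr.ndim != 2:
            raise ValueError("pattern must be 2D (theta, psi)")
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise ValueError("pattern must be finite and nonnegative")
        n_psi = arr.shape[1]
        if abs(n_psi * self.psi_res_deg - 360.0) > 1e-9:
            raise ValueError("azimuth axis must cover the full circle")

    @property
    def theta_max_deg(self) -> float:
        return (self.values.shape[0] - 1) * self.theta_res_deg


@dataclass(frozen=True)
class ComparisonRecord:
    """Summary of one SLI-vs-reference peak comparison.

    ``n_peaks_delta`` is count(SLI) - count(reference);
    ``position_deltas_deg`` holds the signed position differences
    (SLI - reference, wrapped to (-180, 180]) of the matched peak pairs;
    ``diff_sum`` is the sum of absolute profile differences if the profiles
    were compared, else NaN.
    """

    n_peaks_delta: int
    position_deltas_deg: tuple[float, ...]
    diff_sum: float = float("nan")


def normalize_minmean(p: "AngularProfile | np.ndarray"):
    """Min-subtract then mean-divide normalization for profile comparison.

    ``q = p - min(p)`` followed by ``q / mean(q)``: the output has minimum
    0 and mean 1.  "Average signal intensity" is taken as the mean of the
    min-subtracted profile; accepting bare arrays lets short hand-built
    examples bypass the full-profile invariants.
    """
    if isinstance(p, AngularProfile):
        vals = p.values
    else:
        vals = np.asarray(p, dtype=float)
    q = vals - vals.min()
    m = q.mean()
    if m <= 0:
        raise DegenerateProfileError("degenerate: constant profile")
    out = q / m
    if isinstance(p, AngularProfile):
        return AngularProfile(out, step_deg=p.step_deg, start_deg=p.start_deg)
    return out


def _interp_circular(
    target_angles: np.ndarray, src: AngularProfile
) -> np.ndarray:
    """Linearly interpolate a periodic profile at the target azimuths."""
    src_ang = src.angles_deg % 360.0
    order = np.argsort(src_ang)
    ang = src_ang[order]
    val = src.values[order]
    ang_ext = np.concatenate([ang, [ang[0] + 360.0]])
    val_ext = np.concatenate([val, [val[0]]])
    t = (np.asarray(target_angles) - ang[0]) % 360.0 + ang[0]
    return np.interp(t, ang_ext, val_ext)


def profile_difference_sum(a: AngularProfile, b: AngularProfile) -> float:
    """Sum of absolute differences between two profiles on ``a``'s grid.

    If the grids differ, ``b`` is circularly linearly interpolated onto
    ``a``'s azimuths first.  Symmetric on a shared grid, zero iff the
    profiles agree on the grid, and satisfies the triangle inequality.
    """
    if a.n == b.n and abs(a.step_deg - b.step_deg) < 1e-12 and abs(
        (a.start_deg - b.start_deg) % 360.0
    ) < 1e-12:
        bv = b.values
    else:
        bv = _interp_circular(a.angles_deg, b)
    return float(np.sum(np.abs(a.values - bv)))


def _circ_dist(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def _wrap_signed(d: float) -> float:
    """Wrap a difference to (-180, 180]."""
    w = (d + 180.0) % 360.0 - 180.0
    return 180.0 if w == -180.0 else w


def match_peak_sets(
    sli_positions: list[float],
    ref_positions: list[float],
    match_tol_deg: float = 30.0,
) -> ComparisonRecord:
    """Match two corrected-peak-position sets and report their differences.

    Peaks are assigned one-to-one so that the total circular distance is
    minimal (Hungarian assignment); pairs farther apart than
    ``match_tol_deg`` stay unmatched.  ``n_peaks_delta`` compares the raw
    counts; the signed position deltas (SLI - reference) of the matched
    pairs are wrapped to (-180, 180].

    The caller supplies each technique's thresholded peak set (typically
    prominence >= 8% for SLI and >= 3% for finely sampled scatterometry
    profiles).
    """
    delta_n = len(sli_positions) - len(ref_positions)
    if not sli_positions or not ref_positions:
        return ComparisonRecord(delta_n, ())
    cost = np.array(
        [[_circ_dist(s, r) for r in ref_positions] for s in sli_positions]
    )
    rows, cols = linear_sum_assignment(cost)
    deltas = []
    for i, j in zip(rows, cols):
        if cost[i, j] <= match_tol_deg:
            deltas.append(_wrap_signed(sli_positions[i] - ref_positions[j]))
    return ComparisonRecord(delta_n, tuple(deltas))


def compare_profiles(
    sli: AngularProfile,
    ref: AngularProfile,
    sli_threshold: float = 0.08,
    ref_threshold: float = 0.03,
    match_tol_deg: float = 30.0,
) -> ComparisonRecord:
    """Full SLI-vs-reference profile comparison.

    Both profiles are min-mean normalized; peaks are detected and
    position-corrected at each technique's prominence threshold (8% for the
    coarse SLI profile, 3% for the finely sampled reference, whose denser
    grid separates signal from noise better), matched one-to-one, and the
    sum of absolute profile differences is evaluated on the SLI grid.
    """
    from .peakline import analyze_profile

    a = normalize_minmean(sli)
    b = normalize_minmean(ref)
    _, sli_peaks = analyze_profile(a, prominence_threshold=sli_threshold)
    _, ref_peaks = analyze_profile(b, prominence_threshold=ref_threshold)
    rec = match_peak_sets(
        [pk.position_deg for pk in sli_peaks],
        [pk.position_deg for pk in ref_peaks],
        match_tol_deg=match_tol_deg,
    )
    return ComparisonRecord(
        rec.n_peaks_delta, rec.position_deltas_deg, profile_difference_sum(a, b)
    )


def line_profile_from_pattern(
    pat: ScatteringPattern,
    blur_fwhm_deg: float = 8.0,
    circle_theta_deg: float = 48.0,
    out_step_deg: float | None = None,
    fwhm_is_two_sigma: bool = False,
) -> AngularProfile:
    """Azimuthal line profile of a scattering pattern.

    The pattern is blurred with a 2D Gaussian in angular space (default
    diameter 8 deg, matching the finite illumination aperture; interpreted
    as the FWHM, or as 2 sigma with ``fwhm_is_two_sigma``), with the
    azimuth axis treated circularly, then sampled along the
    ``theta = circle_theta_deg`` ring — the polar angle of the oblique SLI
    illumination — at ``out_step_deg`` (default: the pattern's native
    azimuth resolution).
    """
    if not 0.0 <= circle_theta_deg <= pat.theta_max_deg:
        raise ValueError(
            f"theta {circle_theta_deg} outside pattern range "
            f"[0, {pat.theta_max_deg}]"
        )
    divisor = 2.0 if fwhm_is_two_sigma else GAUSSIAN_FWHM_TO_SIGMA
    sigma_deg = blur_fwhm_deg / divisor
    blurred = gaussian_filter(
        pat.values,
        sigma=(sigma_deg / pat.theta_res_deg, sigma_deg / pat.psi_res_deg),
        mode=("nearest", "wrap"),
    )
    # Linear interpolation between the two theta rows bracketing the ring.
    pos = circle_theta_deg / pat.theta_res_deg
    lo = int(math.floor(pos))
    hi = min(lo + 1, blurred.shape[0] - 1)
    frac = pos - lo
    ring = (1.0 - frac) * blurred[lo] + frac * blurred[hi]
    step = pat.psi_res_deg if out_step_deg is None else out_step_deg
    n_out = int(round(360.0 / step))
    if abs(n_out * step - 360.0) > 1e-9:
        raise ValueError(f"step {step} does not divide 360")
    native = AngularProfile(ring, step_deg=pat.psi_res_deg)
    if n_out == native.n:
        return native
    values = _interp_circular(step * np.arange(n_out), native)
    return AngularProfile(values, step_deg=step)


def direction_difference_map(
    sli_dir: MapImage, ref_dir: MapImage
) -> MapImage:
    """Per-pixel axial direction difference SLI - reference.

    Differences are wrapped to (-90, 90] (axial angles repeat every
    180 deg; an exact 90-deg difference reports +90).  Pixels undefined in
    either input are undefined in the output; the output sentinel is NaN,
    since -1 is a legitimate difference value.
    """
    if sli_dir.data.shape != ref_dir.data.shape:
        raise ValueError("direction maps must share the same shape")
    a = sli_dir.data.astype(float)
    b = ref_dir.data.astype(float)
    diff = (a - b + 90.0) % 180.0 - 90.0
    diff = np.where(diff == -90.0, 90.0, diff)
    defined = sli_dir.defined_mask & ref_dir.defined_mask
    out = np.where(defined, diff, np.nan)
    return MapImage(out, "dir_diff", float("nan"))


def binned_std(
    values: MapImage,
    binner: MapImage,
    bin_width: float = 0.1,
) -> list[tuple[float, float, int]]:
    """Population standard deviation of ``values`` binned by ``binner``.

    Returns ``(bin_left_edge, sigma, n)`` rows for bins
    ``[k*w, (k+1)*w)`` covering [0, 1]; only pixels defined in both maps
    count.  Empty bins report ``n = 0`` and NaN sigma.  Typical use: the
    spread of the SLI-vs-PLI direction difference as a function of
    retardation (low retardation = steep or disordered fibers, where the
    in-plane direction is intrinsically less well defined).
    """
    if values.data.shape != binner.data.shape:
        raise ValueError("maps must share the same shape")
    defined = values.defined_mask & binner.defined_mask
    v = values.data[defined].astype(float)
    b = binner.data[defined].astype(float)
    n_bins = int(math.ceil(1.0 / bin_width))
    rows = []
    for k in range(n_bins):
        left = k * bin_width
        right = left + bin_width
        sel = (b >= left) & (b < right)
        if k == n_bins - 1:
            sel |= b == 1.0
        vals = v[sel]
        if vals.size:
            rows.append((left, float(np.std(vals)), int(vals.size)))
        else:
            rows.append((left, float("nan"), 0))
    return rows


def retardation_from_inclination(alpha_deg: float, ret_max: float) -> float:
    """Retardation |sin delta| of a fiber inclined by ``alpha_deg``.

    ``|sin(arcsin(ret_max) * cos^2 alpha)|``: equals ``ret_max`` for
    in-plane fibers (alpha = 0) and falls monotonically to 0 for vertical
    fibers (alpha = 90 deg).  ``ret_max`` is the maximum retardation of
    the section, absorbing thickness and birefringence.
    """
    if not 0.0 <= ret_max <= 1.0:
        raise ValueError("ret_max must be in [0, 1]")
    if not 0.0 <= alpha_deg <= 90.0:
        raise ValueError("alpha_deg must be in [0, 90]")
    a = math.radians(alpha_deg)
    return abs(math.sin(math.asin(ret_max) * math.cos(a) ** 2))
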