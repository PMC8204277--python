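"""Synthetic SLI profiles and phantom stacks with known ground truth.

The generator emulates the signal model behind SLI: an in-plane fiber
bundle with axial direction ``phi_f`` scatters light into two azimuthal
lobes at ``phi_f +/- 90`` deg, so its profile is a pair of peaks 180 deg
apart.  Crossing bundles superimpose their peak pairs (4 peaks for two
bundles, 6 for three).  Out-of-plane inclination is modeled through its
observable signature only: the peak pair of an inclined bundle moves
together, broadens, and loses prominence until it merges into one broad
peak.  Here that is parameterized by the half-separation ``s``: the two
peaks sit at ``phi_f +/- s``, so ``s = 90`` is the in-plane case with
peaks exactly 180 deg apart (at ``phi_f +/- 90``) and ``s -> 0`` is the
steep case where the peaks merge into a single peak at ``phi_f`` — which
is exactly where the single-peak direction rule expects it.  The true
quantitative mapping between ``s`` and the anatomical inclination angle is
not modeled (it is not known); ``90 - s`` is a monotone proxy only.

Peaks are wrapped Gaussians (the physical peak shape is not specified by
the scattering model; a smooth unimodal bump of adjustable width is all
the analysis chain assumes).  Optional multiplicative Gaussian noise
emulates shot/speckle fluctuations.

Phantom stacks mirror the optic-tract crossing experiments: straight
tissue bands crossing at a controlled angle, with overlap regions carrying
the union of the bands' bundles.  Presets ``cross2`` and ``cross3``
reproduce the two- and three-band layouts (e.g. crossing angles 90, 70,
55 deg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .peakline import AngularProfile
from .stack_io import DIRECTION_SENTINEL, MapImage, SLIStack, StackMetadata

__all__ = [
    "Bundle",
    "PhantomSpec",
    "wrapped_gaussian",
    "synth_profile",
    "synth_stack",
    "cross2",
    "cross3",
]

DEFAULT_PEAK_SIGMA_DEG = 20.0


@dataclass(frozen=True)
class Bundle:
    """One fiber bundle contributing a pair of azimuthal peaks.

    Parameters
    ----------
    direction_deg
        Axial fiber direction phi_f in [0, 180).
    half_separation_deg
        Peak half-separation s in (0, 90]; s = 90 places the peaks at
        phi_f +/- 90 (in-plane bundle), smaller s moves them together
        (inclination proxy).
    weight
        Relative peak amplitude (> 0).
    peak_sigma_deg
        Width parameter of the wrapped-Gaussian peaks (> 0); the default
        20 deg matches the width scale of measured profiles.
    """

    direction_deg: float
    half_separation_deg: float = 90.0
    weight: float = 1.0
    peak_sigma_deg: float = DEFAULT_PEAK_SIGMA_DEG

    def __post_init__(self) -> None:
        if not 0.0 <= self.direction_deg < 180.0:
            raise ValueError("direction_deg must be in [0, 180)")
        if not 0.0 < self.half_separation_deg <= 90.0:
            raise ValueError("half_separation_deg must be in (0, 90]")
        if self.weight <= 0 or self.peak_sigma_deg <= 0:
            raise ValueError("weight and peak_sigma_deg must be positive")

    @property
    def peak_positions_deg(self) -> tuple[float, float]:
        """Azimuths of the bundle's two peaks, in [0, 360).

        Placed symmetrically about ``direction_deg`` so that the pair's
        circular midpoint (mod 180) equals the fiber direction for every
        half-separation, and the merged peak of a steep bundle sits at the
        fiber direction itself.
        """
        return (
            (self.direction_deg - self.half_separation_deg) % 360.0,
            (self.direction_deg + self.half_separation_deg) % 360.0,
        )


@dataclass(frozen=True)
class PhantomSpec:
    """Layout of a synthetic phantom stack.

    ``regions`` is a list of ``(mask, bundles)`` pairs; a pixel covered by
    several regions carries the union of their bundles (tissue layers
    stacked on top of each other superimpose their signals).  ``noise_sd``
    is the standard deviation of multiplicative Gaussian noise; ``seed``
    makes generation reproducible and is mandatory.
    """

    shape: tuple[int, int]
    regions: list[tuple[np.ndarray, list[Bundle]]]
    baseline: float = 1.0
    noise_sd: float = 0.0
    seed: int = field(default=0)

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("phantom needs at least one region")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for mask, bundles in self.regions:
            if mask.shape != tuple(self.shape):
                raise ValueError("region mask shape differs from phantom shape")
            if not bundles:
                raise ValueError("region with empty bundle list")


def wrapped_gaussian(x_deg: np.ndarray, sigma_deg: float) -> np.ndarray:
    """Gaussian bump on the circle, evaluated at angular offsets ``x_deg``.

    Sum of Gaussian images at 360-deg shifts; three terms suffice for the
    sigma range used here (the omitted tails are below 1e-12 for
    sigma <= 60 deg).
    """
    x = (np.asarray(x_deg, dtype=float) + 180.0) % 360.0 - 180.0
    s2 = 2.0 * sigma_deg**2
    return (
        np.exp(-x**2 / s2)
        + np.exp(-((x - 360.0) ** 2) / s2)
        + np.exp(-((x + 360.0) ** 2) / s2)
    )


def _noiseless_values(
    bundles: list[Bundle], angles_deg: np.ndarray, baseline: float
) -> np.ndarray:
    out = np.full(angles_deg.shape, float(baseline))
    for b in bundles:
        for pos in b.peak_positions_deg:
            out += b.weight * wrapped_gaussian(angles_deg - pos, b.peak_sigma_deg)
    return out


def synth_profile(
    bundles: list[Bundle],
    step_deg: float = 15.0,
    baseline: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    start_deg: float = 0.0,
) -> tuple[AngularProfile, list[float]]:
    """Generate one profile and its ground-truth direction list.

    The noiseless profile is ``baseline`` plus, per bundle, a pair of
    wrapped-Gaussian peaks of amplitude ``weight`` at the bundle's peak
    positions; multiplicative noise ``(1 + eps)``, ``eps ~ N(0, noise_sd)``
    per sample, is applied on top.  The returned ground truth is the sorted
    list of distinct bundle directions (axial, degrees).
    """
    if not bundles:
        raise ValueError("need at least one bundle")
    n = int(round(360.0 / step_deg))
    if abs(n * step_deg - 360.0) > 1e-9:
        raise ValueError(f"step {step_deg} does not divide 360")
    angles = start_deg + step_deg * np.arange(n)
    values = _noiseless_values(bundles, angles, baseline)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values * (1.0 + rng.normal(0.0, noise_sd, size=n))
        values = np.clip(values, 0.0, None)
    truth = sorted({b.direction_deg % 180.0 for b in bundles})
    return AngularProfile(values, step_deg=step_deg, start_deg=start_deg), truth


def synth_stack(
    spec: PhantomSpec, step_deg: float = 15.0
) -> tuple[SLIStack, dict[str, MapImage]]:
    """Generate a phantom stack and its ground-truth direction maps.

    Each pixel's profile is built from the union of the bundles of all
    regions covering it (signal superposition of stacked tissue layers,
    sharing a single baseline).  Pixels covered by no region get a
    featureless baseline profile.  Ground truth comes back as maps
    ``gt_dir_1..3`` (sorted ascending, sentinel -1 where fewer directions
    or no tissue) plus ``gt_n_dirs``.

    Generation is fully deterministic given ``spec.seed``.
    """
    rows, cols = spec.shape
    n = int(round(360.0 / step_deg))
    if abs(n * step_deg - 360.0) > 1e-9:
        raise ValueError(f"step {step_deg} does not divide 360")
    angles = step_deg * np.arange(n)

    # Key pixels by the subset of regions covering them; one noiseless
    # profile per distinct subset.
    region_bits = np.zeros((rows, cols), dtype=np.int64)
    for k, (mask, _) in enumerate(spec.regions):
        region_bits[mask] |= 1 << k

    data = np.empty((rows, cols, n), dtype=float)
    profiles: dict[int, np.ndarray] = {}
    truths: dict[int, list[float]] = {}
    for bits in np.unique(region_bits):
        bundles = [
            b
            for k, (_, bl) in enumerate(spec.regions)
            if bits & (1 << k)
            for b in bl
        ]
        if bundles:
            profiles[bits] = _noiseless_values(bundles, angles, spec.baseline)
            truths[bits] = sorted({b.direction_deg % 180.0 for b in bundles})
        else:
            profiles[bits] = np.full(n, float(spec.baseline))
            truths[bits] = []
        data[region_bits == bits] = profiles[bits]

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data * (1.0 + rng.normal(0.0, spec.noise_sd, size=data.shape))
        data = np.clip(data, 0.0, None)

    gt = np.full((3, rows, cols), DIRECTION_SENTINEL, dtype=np.float32)
    n_dirs = np.zeros((rows, cols), dtype=np.float32)
    for bits, dirs in truths.items():
        sel = region_bits == bits
        n_dirs[sel] = len(dirs)
        for k, d in enumerate(dirs[:3]):
            gt[k][sel] = d
    stack = SLIStack(data=data, meta=StackMetadata(step_deg=step_deg))
    gt_maps = {
        "gt_dir_1": MapImage(gt[0], "gt_dir_1", DIRECTION_SENTINEL),
        "gt_dir_2": MapImage(gt[1], "gt_dir_2", DIRECTION_SENTINEL),
        "gt_dir_3": MapImage(gt[2], "gt_dir_3", DIRECTION_SENTINEL),
        "gt_n_dirs": MapImage(n_dirs, "gt_n_dirs", float("nan")),
    }
    return stack, gt_maps


def _band_mask(
    shape: tuple[int, int], direction_deg: float, halfwidth: float
) -> np.ndarray:
    """Pixels within ``halfwidth`` of the center line along ``direction_deg``.

    Image coordinates: x = column, y = row (growing downward); direction 0
    points up (twelve o'clock) and increases clockwise, matching the
    azimuth convention of the directions themselves.
    """
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    phi = np.radians(direction_deg)
    # Unit normal to the line direction (sin phi, -cos phi) in (x, y).
    dist = (xx - cx) * np.cos(phi) + (yy - cy) * np.sin(phi)
    return np.abs(dist) <= halfwidth


def _cross_spec(
    directions: list[float],
    shape: tuple[int, int],
    band_halfwidth: float | None,
    noise_sd: float,
    seed: int,
    peak_sigma_deg: float,
) -> PhantomSpec:
    if band_halfwidth is None:
        band_halfwidth = min(shape) / 5.0
    regions = [
        (
            _band_mask(shape, d, band_halfwidth),
            [Bundle(direction_deg=d % 180.0, peak_sigma_deg=peak_sigma_deg)],
        )
        for d in directions
    ]
    return PhantomSpec(
        shape=shape, regions=regions, noise_sd=noise_sd, seed=seed
    )


def cross2(
    angle_deg: float,
    shape: tuple[int, int] = (40, 40),
    band_halfwidth: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    peak_sigma_deg: float = DEFAULT_PEAK_SIGMA_DEG,
) -> PhantomSpec:
    """Two straight in-plane bands crossing at ``angle_deg`` in the center.

    Band directions are ``90 -/+ angle/2`` so the crossing is symmetric
    about the vertical axis; the overlap region carries both bundles.
    """
    if not 0 < angle_deg <= 90:
        raise ValueError("crossing angle must be in (0, 90]")
    dirs = [(90.0 - angle_deg / 2.0) % 180.0, (90.0 + angle_deg / 2.0) % 180.0]
    return _cross_spec(dirs, shape, band_halfwidth, noise_sd, seed, peak_sigma_deg)


def cross3(
    angle_deg: float,
    shape: tuple[int, int] = (40, 40),
    band_halfwidth: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    peak_sigma_deg: float = DEFAULT_PEAK_SIGMA_DEG,
) -> PhantomSpec:
    """Three straight bands with consecutive crossing angles ``angle_deg``."""
    if not 0 < angle_deg <= 60:
        raise ValueError("crossing angle must be in (0, 60] for three bands")
    dirs = [
        (90.0 - angle_deg) % 180.0,
        90.0,
        (90.0 + angle_deg) % 180.0,
    ]
    return _cross_spec(dirs, shape, band_halfwidth, noise_sd, seed, peak_sigma_deg)
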