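import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from slimaps import AngularProfile

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# Two-peak profile at 15-deg steps: triangular peaks of value 5 at samples
# 2 and 14 (azimuths 30 and 210 deg) over a baseline of 1.
F24_VALUES = np.array(
    [1, 2, 5, 2, 1, 1, 1, 1, 1, 1, 1, 1, 1, 2, 5, 2, 1, 1, 1, 1, 1, 1, 1, 1],
    dtype=float,
)


@pytest.fixture
def f24() -> AngularProfile:
    return AngularProfile(F24_VALUES.copy(), step_deg=15.0)


@pytest.fixture
def f24b() -> AngularProfile:
    """F24 with sample 3 raised to 4: an asymmetric right flank on peak 2."""
    vals = F24_VALUES.copy()
    vals[3] = 4.0
    return AngularProfile(vals, step_deg=15.0)


def brute_force_circular_peaks(values) -> list[int]:
    """Independent oracle: exhaustive circular local-maximum scan.

    For every index, expands its plateau of equal values in both circular
    directions and reports the plateau's center sample (rounding to the
    lower index) when both plateau neighbors are strictly smaller.
    """
    v = list(values)
    n = len(v)
    out = []
    for i in range(n):
        left = i
        while v[(left - 1) % n] == v[i] and (i - left) < n:
            left -= 1
        right = i
        while v[(right + 1) % n] == v[i] and (right - i) < n:
            right += 1
        if right - left + 1 >= n:
            continue  # constant profile
        if v[(left - 1) % n] < v[i] and v[(right + 1) % n] < v[i]:
            center = (left + (right - left) // 2) % n
            if center == i % n:
                out.append(i)
    return sorted(out)
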