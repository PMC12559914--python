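"""Shared fixtures and independent geometric oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.optimize import minimize

from fidplan import PhantomSpec, generate_phantom

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def point_to_ellipsoid_distance(q, centroid, semi_axes) -> float:
    """Numeric distance from a point to an ellipsoid surface.

    Independent oracle: minimises ||q - E(theta, phi)|| over the
    spherical parameterization of the ellipsoid, started from the
    direction of q (the ellipsoid is convex, so the radial start is in
    the basin of the global minimum).
    """
    q = np.asarray(q, float) - np.asarray(centroid, float)
    a, b, c = semi_axes

    def surf(x):
        th, ph = x
        return np.array([a * np.sin(th) * np.cos(ph),
                         b * np.sin(th) * np.sin(ph),
                         c * np.cos(th)])

    def obj(x):
        return np.linalg.norm(q - surf(x))

    r = np.linalg.norm(q)
    th0 = np.arccos(np.clip(q[2] / r, -1, 1))
    ph0 = np.arctan2(q[1], q[0])
    best = np.inf
    for dth in (0.0, 0.15, -0.15):
        for dph in (0.0, 0.2, -0.2):
            res = minimize(obj, [th0 + dth, ph0 + dph], method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12})
            best = min(best, res.fun)
    return float(best)


@pytest.fixture(scope="session")
def sphere_phantom():
    """The reference superficial-tumor phantom: 15 mm sphere, 20-30 mm shell."""
    spec = PhantomSpec(seed=42)
    tumor, shell, cen = generate_phantom(spec)
    return spec, tumor, shell, cen


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
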