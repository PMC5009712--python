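"""Planar geometry primitives: Minkowski L1/L2 metrics and rotation.

All coordinates are planar, projected metres.  Distances are computed with
two Minkowski metrics: L2 (Euclidean) and L1 (Manhattan / rectilinear).  L2
is rotation-invariant; L1 is not, which is exploited downstream by sweeping
the L1 metric over coordinate rotations to bound the bias introduced by
assuming straight-line Euclidean separation in a grid-like street network.
Rotating the frame by 90 degrees maps the L1 metric onto itself, so rotation
angles are meaningful on [0, 90) degrees only.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "Metric",
    "as_coords",
    "l1_distance",
    "l2_distance",
    "rotate_points",
    "rotation_matrix",
]


def as_coords(points) -> np.ndarray:
    """Coerce input to an (n, 2) float64 coordinate array and validate it.

    Accepts an (n, 2) array-like or a single (x, y) pair.  Raises
    ``ValueError`` on non-finite coordinates or a wrong shape.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim == 1:
        if arr.shape != (2,):
            raise ValueError(f"a point must have exactly 2 coordinates, got shape {arr.shape}")
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) coordinate array, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError("coordinates must be finite (no NaN/Inf)")
    return arr


def _pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    pa, pb = as_coords(a), as_coords(b)
    if len(pa) != 1 or len(pb) != 1:
        raise ValueError("distance functions take single points; use Metric.pairwise for sets")
    return pa[0], pb[0]


def l2_distance(a, b) -> float:
    """Euclidean (Minkowski L2) distance between two points, in metres."""
    pa, pb = _pair(a, b)
    return float(math.hypot(pa[0] - pb[0], pa[1] - pb[1]))


def l1_distance(a, b) -> float:
    """Manhattan / rectilinear (Minkowski L1) distance |dx| + |dy|, in metres."""
    pa, pb = _pair(a, b)
    return float(abs(pa[0] - pb[0]) + abs(pa[1] - pb[1]))


def rotation_matrix(theta_deg: float) -> np.ndarray:
    """Counter-clockwise rotation matrix for an angle given in degrees."""
    t = math.radians(theta_deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s], [s, c]])


def rotate_points(points, theta_deg: float) -> np.ndarray:
    """Rotate points counter-clockwise about the coordinate origin.

    The rotation centre is deliberately the origin, not the point-set
    centroid: only pairwise distances are consumed downstream, for which the
    centre is immaterial — L2 distances are preserved exactly and L1
    distances depend only on the orientation of the frame.
    """
    coords = as_coords(points)
    return coords @ rotation_matrix(theta_deg).T


@dataclasses.dataclass(frozen=True)
class Metric:
    """A pairwise distance metric: L2, or L1 evaluated in a rotated frame.

    Parameters
    ----------
    kind : {"l2", "l1"}
        Minkowski order.  ``"l2"`` ignores ``theta`` (rotation-invariant).
    theta : float
        Frame rotation in degrees applied before measuring L1 distances.
        Analysis sweeps restrict themselves to [0, 90] since L1 has period
        90; the type itself accepts any finite angle (e.g. to verify the
        period-90 symmetry).
    """

    kind: str = "l2"
    theta: float = 0.0

    def __post_init__(self):
        if self.kind not in ("l1", "l2"):
            raise ValueError(f"metric kind must be 'l1' or 'l2', got {self.kind!r}")
        if not math.isfinite(self.theta):
            raise ValueError("rotation angle must be finite")

    @property
    def tag(self) -> str:
        return "L2" if self.kind == "l2" else f"L1@{self.theta:g}deg"

    def pairwise(self, points) -> np.ndarray:
        """Condensed pairwise distance vector (scipy ``pdist`` layout)."""
        coords = as_coords(points)
        if self.kind == "l2":
            return pdist(coords, metric="euclidean")
        if self.theta != 0.0:
            coords = rotate_points(coords, self.theta)
        return pdist(coords, metric="cityblock")

    def distance(self, a, b) -> float:
        if self.kind == "l2":
            return l2_distance(a, b)
        ra = rotate_points(a, self.theta)[0]
        rb = rotate_points(b, self.theta)[0]
        return l1_distance(ra, rb)


def coerce_metric(metric) -> Metric:
    """Accept a Metric, or a string like 'l2' / 'l1'."""
    if isinstance(metric, Metric):
        return metric
    if isinstance(metric, str):
        return Metric(kind=metric.lower())
    raise TypeError(f"cannot interpret {metric!r} as a metric")
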