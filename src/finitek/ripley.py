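"""Finite-location Ripley's K estimation.

The estimator here differs from textbook Ripley's K in two deliberate ways,
both driven by the finite-location setting (events can only occur at an
enumerated set of candidate sites, e.g. residential parcel centroids):

* the intensity normaliser is ``lambda = q / D`` where ``D`` is the maximum
  pairwise Euclidean distance of a reference point set — a 1/length quantity
  rather than the usual 1/area one; and
* no edge correction is applied, because inference is against a Monte-Carlo
  null drawn from the same bounded candidate set, so boundary effects are
  shared by the observed and simulated patterns and cancel by construction.

Because the envelope test is a rank test, any shared positive normaliser
leaves significance unchanged; ``lambda`` affects only the scale on which K
is displayed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .geometry import Metric, as_coords, coerce_metric

__all__ = [
    "MarkedLocationSet",
    "CaseSet",
    "KEstimate",
    "as_thresholds",
    "cumulative_pair_counts",
    "estimate_intensity",
    "max_pairwise_distance",
    "ripley_k",
]


@dataclasses.dataclass(frozen=True)
class MarkedLocationSet:
    """The finite universe of candidate event locations with integer marks.

    This is the constrained sampling space: every observed or simulated
    event must sit at one of these sites.  ``marks`` carries a per-site
    integer covariate level (e.g. an area deprivation decile 1..10).

    Parameters
    ----------
    coords : (n, 2) float array
        Planar site coordinates in projected metres.
    marks : (n,) int array
        Integer mark per site, drawn from a finite mark set.
    ids : (n,) array, optional
        Stable site identifiers; defaults to ``0..n-1``.
    """

    coords: np.ndarray
    marks: np.ndarray
    ids: np.ndarray = None

    def __post_init__(self):
        coords = as_coords(self.coords)
        marks = np.asarray(self.marks)
        if not np.issubdtype(marks.dtype, np.integer):
            as_int = np.asarray(self.marks, dtype=np.int64)
            if not np.array_equal(as_int, np.asarray(self.marks, dtype=float)):
                raise ValueError("marks must be integers")
            marks = as_int
        if len(coords) < 1:
            raise ValueError("a location set needs at least one site")
        if len(marks) != len(coords):
            raise ValueError("coords and marks must have equal length")
        ids = self.ids
        if ids is None:
            ids = np.arange(len(coords))
        ids = np.asarray(ids)
        if len(ids) != len(coords):
            raise ValueError("ids and coords must have equal length")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "marks", marks)
        object.__setattr__(self, "ids", ids)

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def mark_set(self) -> np.ndarray:
        """Distinct marks present, sorted."""
        return np.unique(self.marks)


@dataclasses.dataclass(frozen=True)
class CaseSet:
    """Indices of observed (or simulated) event sites within a location set.

    Indices must be distinct: the study design keeps one index episode per
    location, so an event pattern is a subset of sites, not a multiset.
    """

    indices: np.ndarray

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.ndim != 1 or len(idx) < 1:
            raise ValueError("a case set needs at least one index")
        if len(np.unique(idx)) != len(idx):
            raise ValueError("case indices must be distinct")
        if (idx < 0).any():
            raise ValueError("case indices must be non-negative")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def coords(self, locations: MarkedLocationSet) -> np.ndarray:
        if self.indices.max() >= len(locations):
            raise ValueError("case index out of range for this location set")
        return locations.coords[self.indices]

    def marks(self, locations: MarkedLocationSet) -> np.ndarray:
        if self.indices.max() >= len(locations):
            raise ValueError("case index out of range for this location set")
        return locations.marks[self.indices]


def as_thresholds(r) -> np.ndarray:
    """Validate a distance-threshold grid: strictly increasing, all > 0."""
    arr = np.asarray(r, dtype=float)
    if arr.ndim != 1 or len(arr) == 0:
        raise ValueError("thresholds must be a non-empty 1-D sequence")
    if not np.isfinite(arr).all():
        raise ValueError("thresholds must be finite")
    if arr[0] <= 0 or (np.diff(arr) <= 0).any():
        raise ValueError("thresholds must be positive and strictly increasing")
    return arr


def default_thresholds(start: float = 25.0, stop: float = 1000.0, step: float = 25.0) -> np.ndarray:
    """Default analysis grid: 25 m to 1000 m in 25 m steps."""
    return np.arange(start, stop + step / 2, step)


def max_pairwise_distance(points) -> float:
    """Maximum pairwise Euclidean distance (the point-set diameter).

    For large sets the diameter is realised on the convex hull, so the
    exhaustive pair scan is restricted to hull vertices.
    """
    coords = as_coords(points)
    if len(coords) < 2:
        raise ValueError("need at least two points for a pairwise distance")
    if len(coords) > 500:
        try:
            coords = coords[ConvexHull(coords).vertices]
        except Exception:  # degenerate (e.g. collinear) input: fall through
            pass
    return float(pdist(coords, metric="euclidean").max())


def estimate_intensity(case_set: CaseSet, locations: MarkedLocationSet,
                       reference: str = "cases") -> float:
    """Intensity normaliser ``lambda = q / max pairwise L2 distance``.

    ``reference`` selects the point set whose diameter is used: ``"cases"``
    (the pattern under evaluation) or ``"universe"`` (all candidate sites,
    giving a single fixed normaliser shared by observed and null patterns —
    the convention used for envelope testing, under which the rank test is
    exactly invariant to lambda).
    """
    q = len(case_set)
    if q < 2:
        raise ValueError("intensity needs at least two cases")
    if reference == "cases":
        pts = case_set.coords(locations)
    elif reference == "universe":
        pts = locations.coords
    else:
        raise ValueError(f"unknown lambda reference {reference!r}")
    d = max_pairwise_distance(pts)
    if d == 0:
        raise ValueError("all reference points coincide; intensity undefined")
    return q / d


def cumulative_pair_counts(points, thresholds, metric: Metric | str = "l2") -> np.ndarray:
    """Total ordered-pair counts within each distance threshold.

    For each threshold ``r`` returns ``sum_j #{k != j : d(p_j, p_k) <= r}``.
    Each unordered pair contributes twice, so every count is even, and the
    vector is non-decreasing in ``r``.  The ball is closed (``<= r``).
    """
    coords = as_coords(points)
    if len(coords) < 2:
        raise ValueError("pair counting needs at least two points")
    r = as_thresholds(thresholds)
    metric = coerce_metric(metric)
    d = np.sort(metric.pairwise(coords))
    return 2 * np.searchsorted(d, r, side="right").astype(np.int64)


@dataclasses.dataclass(frozen=True)
class KEstimate:
    """Ripley's K over a threshold grid under one metric.

    ``k_values[i] = (pair_counts[i] / q) / lambda`` — the per-point mean
    number of other events within ``r_i``, divided by the intensity.
    ``scaled_values`` is the display scaling ``lambda**2 * K(r)`` (the
    expected number of events within ``r``); it is kept separate from the
    inference path.
    """

    thresholds: np.ndarray
    k_values: np.ndarray
    lam: float
    metric: Metric
    pair_counts: np.ndarray

    @property
    def scaled_values(self) -> np.ndarray:
        return self.lam ** 2 * self.k_values

    def __len__(self) -> int:
        return len(self.thresholds)


def k_from_counts(counts: np.ndarray, q: int, lam: float, thresholds: np.ndarray,
                  metric: Metric) -> KEstimate:
    k = counts / q / lam
    return KEstimate(thresholds=thresholds, k_values=k, lam=lam, metric=metric,
                     pair_counts=np.asarray(counts))


def ripley_k(case_set: CaseSet, locations: MarkedLocationSet, thresholds,
             metric: Metric | str = "l2", lambda_reference: str = "cases",
             lam: float | None = None) -> KEstimate:
    """Finite-location Ripley's K for an event pattern.

    Parameters
    ----------
    case_set, locations
        The event pattern and the candidate universe it indexes into.
    thresholds
        Strictly increasing positive distances (metres).
    metric
        ``"l2"``, ``"l1"`` or a :class:`~finitek.geometry.Metric` (L1 with a
        frame rotation).
    lambda_reference
        Point set for the intensity normaliser (see
        :func:`estimate_intensity`); ignored when ``lam`` is given.
    lam
        Explicit pre-computed intensity, used by envelope construction so
        observed and simulated K share one normaliser.
    """
    r = as_thresholds(thresholds)
    metric = coerce_metric(metric)
    if lam is None:
        lam = estimate_intensity(case_set, locations, reference=lambda_reference)
    if lam <= 0:
        raise ValueError("intensity must be positive")
    pts = case_set.coords(locations)
    counts = cumulative_pair_counts(pts, r, metric)
    return k_from_counts(counts, len(case_set), lam, r, metric)
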