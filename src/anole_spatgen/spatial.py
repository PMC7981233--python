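"""Park geometry: bush distance matrices, home-range polygons, average distances.

Two inter-bush metrics are provided.  ``euclidean`` is the straight-line
distance between bush centroids.  ``perimeter`` is the shorter of the two
along-fence arc lengths between the centroids' perpendicular projections onto
the fence polyline — appropriate when the open park interior is not a
dispersal corridor and animals move along the fence-line vegetation.

Home ranges are built from capture bushes: a single distinct bush yields that
bush's polygon; two or more yield the convex hull of the union of the capture
bush polygons (the smallest deterministic region containing the distal capture
points and all area between them).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .io import HabitatMap, Individual

__all__ = [
    "DistanceMatrix",
    "HomeRange",
    "AverageDistance",
    "bush_distance_matrix",
    "home_range",
    "home_ranges",
    "average_distance",
    "individual_distance_matrix",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances (m) over bushes or individuals."""

    ids: list
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        self.values = v
        self._index = {i: k for k, i in enumerate(self.ids)}

    def get(self, a, b) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, ids: Sequence) -> "DistanceMatrix":
        idx = [self._index[i] for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)], self.metric)


@dataclass
class HomeRange:
    """An individual's home-range polygon spanned by its capture bushes."""

    individual_id: str
    bush_ids: list[int]
    polygon: Polygon
    area: float
    n_capture_cohorts: int

    @property
    def single_bush(self) -> bool:
        return len(self.bush_ids) == 1


@dataclass
class AverageDistance:
    """Mean distance d' from a focal male to the other males of its cohort."""

    focal_id: str
    cohort_label: str
    d_prime: float
    n: int  # cohort male count including the focal
    components: list[float]


def bush_distance_matrix(habitat: HabitatMap, metric: str = "perimeter") -> DistanceMatrix:
    """Centroid-to-centroid distances between all bushes under a metric."""
    ids = habitat.bush_ids
    cents = np.array([habitat.centroid(b) for b in ids])
    if metric == "euclidean":
        diff = cents[:, None, :] - cents[None, :, :]
        vals = np.sqrt((diff**2).sum(axis=2))
    elif metric == "perimeter":
        fence = habitat.fence
        total = fence.length
        # arc position of each centroid's perpendicular projection onto the fence
        s = np.array([fence.project(habitat.bushes[b].centroid) for b in ids])
        gap = np.abs(s[:, None] - s[None, :])
        vals = np.minimum(gap, total - gap)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(ids, vals, metric)


def home_range(individual: Individual, habitat: HabitatMap) -> HomeRange:
    """Home-range polygon from an individual's capture bushes."""
    if not individual.records:
        raise ValueError(f"{individual.individual_id}: no capture records")
    bush_ids = individual.capture_bushes
    polys = [habitat.bushes[b] for b in bush_ids]
    if len(bush_ids) == 1:
        poly = polys[0]
    else:
        poly = unary_union(polys).convex_hull
    return HomeRange(
        individual_id=individual.individual_id,
        bush_ids=bush_ids,
        polygon=poly,
        area=poly.area,
        n_capture_cohorts=len({r.cohort for r in individual.records}),
    )


def home_ranges(
    individuals: Iterable[Individual],
    habitat: HabitatMap,
    exclude_single_capture: bool = False,
) -> dict[str, HomeRange]:
    out = {}
    for ind in individuals:
        hr = home_range(ind, habitat)
        if exclude_single_capture and hr.n_capture_cohorts < 2:
            continue
        out[ind.individual_id] = hr
    return out


def average_distance(
    focal_id: str,
    cohort_males: dict[str, int],
    dmat: DistanceMatrix,
    cohort_label: str = "",
) -> AverageDistance:
    """d' = mean bush distance from the focal male to every other cohort male.

    ``cohort_males`` maps male id -> capture bush id for one cohort.  Males
    captured in the focal's bush contribute distance 0 (a floor effect of
    bush-centroid coarsening).
    """
    if focal_id not in cohort_males:
        raise ValueError(f"focal {focal_id} not in cohort males")
    n = len(cohort_males)
    if n < 2:
        raise ValueError(f"cohort has {n} male(s); d' undefined for n < 2")
    fb = cohort_males[focal_id]
    comps = [
        dmat.get(fb, b) for other, b in cohort_males.items() if other != focal_id
    ]
    return AverageDistance(
        focal_id=focal_id,
        cohort_label=cohort_label,
        d_prime=float(np.mean(comps)),
        n=n,
        components=comps,
    )


def individual_distance_matrix(
    positions: dict[str, int], dmat: DistanceMatrix
) -> DistanceMatrix:
    """Distances between individuals, via the bushes they occupy."""
    ids = list(positions)
    n = len(ids)
    vals = np.zeros((n, n))
    for i, a in enumerate(ids):
        for j in range(i + 1, n):
            d = dmat.get(positions[a], positions[ids[j]])
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(ids, vals, dmat.metric)
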