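"""Multimorbidity-weighted burden index and its discretization into ordered states.

The burden index of an individual is the sum of severity weights of the
chronic diseases they currently report.  Enumerating every subset of the
disease list ("cluster") maps out all attainable index values; an exact
one-dimensional k-means then splits the index line into ``k`` ordered burden
states (S1 = lightest ... Sk = heaviest).

The k-means here is the deterministic dynamic-programming optimum, not a
Lloyd iteration: in one dimension the optimal clusters are contiguous in
sorted order, so the globally minimal within-cluster sum of squares can be
found exactly by DP over split points.  This removes any dependence on a
random initialisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "DiseaseWeightTable",
    "StatePartition",
    "compute_burden_index",
    "count_conditions",
    "enumerate_clusters",
    "kmeans_1d",
    "assign_state",
]

#: guard for exhaustive cluster enumeration (2**20 subsets is the refusal point)
MAX_ENUMERABLE_DISEASES = 20


@dataclass(frozen=True)
class DiseaseWeightTable:
    """Disease name -> positive severity weight (dimensionless)."""

    entries: Mapping[str, float]

    def __post_init__(self) -> None:
        entries = dict(self.entries)
        for name, w in entries.items():
            if not np.isfinite(w) or w <= 0:
                raise ValueError(f"weight for disease {name!r} must be > 0, got {w}")
        object.__setattr__(self, "entries", entries)

    @property
    def diseases(self) -> tuple[str, ...]:
        return tuple(sorted(self.entries))

    def __contains__(self, disease: str) -> bool:
        return disease in self.entries

    def __getitem__(self, disease: str) -> float:
        try:
            return self.entries[disease]
        except KeyError:
            raise KeyError(
                f"disease {disease!r} is not in the weight table; "
                "the weight table and the data disagree on disease names"
            ) from None

    @classmethod
    def from_yaml(cls, path) -> "DiseaseWeightTable":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(entries={str(k): float(v) for k, v in data.items()})

    @classmethod
    def from_csv(cls, path) -> "DiseaseWeightTable":
        import pandas as pd

        frame = pd.read_csv(path)
        if frame.shape[1] < 2:
            raise ValueError("weight table file needs two columns: disease, weight")
        col_d, col_w = frame.columns[:2]
        if frame[col_d].duplicated().any():
            raise ValueError("duplicate disease names in weight table")
        return cls(entries=dict(zip(frame[col_d].astype(str), frame[col_w].astype(float))))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: float(v) for k, v in sorted(self.entries.items())}, fh)


def compute_burden_index(disease_set: Iterable[str], weight_table: DiseaseWeightTable) -> float:
    """Sum of weights of the present diseases; the empty set scores 0."""
    return float(sum(weight_table[d] for d in set(disease_set)))


def count_conditions(disease_set: Iterable[str]) -> tuple[int, bool]:
    """Number of distinct conditions and the multimorbidity flag (count >= 2)."""
    n = len(set(disease_set))
    return n, n >= 2


def enumerate_clusters(
    disease_names: Sequence[str], weight_table: DiseaseWeightTable
) -> list[tuple[tuple[str, ...], float]]:
    """All ``2**d`` disease subsets with their burden index, lexicographically.

    The exhaustive enumeration is what maps the attainable index values; it is
    refused above :data:`MAX_ENUMERABLE_DISEASES` diseases.
    """
    names = sorted(set(disease_names))
    if len(names) != len(list(disease_names)):
        raise ValueError("disease names must be unique")
    d = len(names)
    if d > MAX_ENUMERABLE_DISEASES:
        raise ValueError(
            f"refusing to enumerate 2**{d} clusters; the limit is "
            f"{MAX_ENUMERABLE_DISEASES} diseases"
        )
    for name in names:
        weight_table[name]  # raises on unknown disease
    subsets: list[tuple[str, ...]] = []
    for r in range(d + 1):
        subsets.extend(combinations(names, r))
    subsets.sort()
    return [(s, compute_burden_index(s, weight_table)) for s in subsets]


@dataclass(frozen=True)
class StatePartition:
    """Partition of the index line into ``k`` ordered states.

    Interval ``i`` is ``[lower_i, upper_i)`` with the last interval closed
    above at +infinity; a value exactly on a boundary belongs to the higher
    (more severe) state.
    """

    boundaries: tuple[float, ...]
    centroids: tuple[float, ...]
    within_cluster_ss: float
    state_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.boundaries)
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("partition boundaries must be strictly increasing")
        object.__setattr__(self, "boundaries", b)
        object.__setattr__(self, "centroids", tuple(float(c) for c in self.centroids))
        if not self.state_labels:
            object.__setattr__(
                self, "state_labels", tuple(f"S{i + 1}" for i in range(len(b) + 1))
            )
        if len(self.state_labels) != len(b) + 1:
            raise ValueError("need one state label per interval")

    @property
    def k(self) -> int:
        return len(self.boundaries) + 1

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "boundaries": [float(x) for x in self.boundaries],
                    "centroids": [float(x) for x in self.centroids],
                    "within_cluster_ss": float(self.within_cluster_ss),
                    "state_labels": list(self.state_labels),
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "StatePartition":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            boundaries=tuple(data["boundaries"]),
            centroids=tuple(data["centroids"]),
            within_cluster_ss=float(data["within_cluster_ss"]),
            state_labels=tuple(data.get("state_labels", ())),
        )


def kmeans_1d(values: Sequence[float], k: int) -> StatePartition:
    """Globally optimal squared-error clustering of scalars into ``k`` clusters.

    Dynamic programming over contiguous splits of the sorted distinct values
    (with multiplicity weights), exploiting the 1-D optimal-substructure
    property.  Boundaries are midpoints between adjacent-cluster extremes.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1 or vals.size == 0:
        raise ValueError("values must be a non-empty 1-D sequence")
    x, w = np.unique(vals, return_counts=True)
    n = x.size
    if n < k:
        raise ValueError(f"need at least k={k} distinct values, got {n}")
    wf = w.astype(float)
    # prefix sums for O(1) weighted SS of any contiguous block [i, j]
    cw = np.concatenate([[0.0], np.cumsum(wf)])
    cwx = np.concatenate([[0.0], np.cumsum(wf * x)])
    cwx2 = np.concatenate([[0.0], np.cumsum(wf * x * x)])

    def block_cost(i: np.ndarray, j: int) -> np.ndarray:
        # SS of blocks x[i..j] for vector i
        W = cw[j + 1] - cw[i]
        S = cwx[j + 1] - cwx[i]
        S2 = cwx2[j + 1] - cwx2[i]
        return S2 - S * S / W

    cost = np.full((k, n), np.inf)
    split = np.zeros((k, n), dtype=int)
    for j in range(n):
        cost[0, j] = block_cost(np.array([0]), j)[0]
    for m in range(1, k):
        for j in range(m, n):
            i = np.arange(m, j + 1)  # first index of the last cluster
            cand = cost[m - 1, i - 1] + block_cost(i, j)
            best = int(np.argmin(cand))
            cost[m, j] = cand[best]
            split[m, j] = i[best]

    # recover cluster extents
    bounds_idx: list[int] = []
    j = n - 1
    for m in range(k - 1, 0, -1):
        i = split[m, j]
        bounds_idx.append(i)
        j = i - 1
    bounds_idx.reverse()
    starts = [0] + bounds_idx
    ends = bounds_idx + [n]
    centroids = []
    for s, e in zip(starts, ends):
        centroids.append(float((cwx[e] - cwx[s]) / (cw[e] - cw[s])))
    boundaries = tuple(
        float((x[e - 1] + x[e]) / 2.0) for e in bounds_idx
    )
    return StatePartition(
        boundaries=boundaries,
        centroids=tuple(centroids),
        within_cluster_ss=float(cost[k - 1, n - 1]),
    )


def assign_state(index_value: float, partition: StatePartition) -> str:
    """Map an index value to its burden state label (ties go to the higher state)."""
    if index_value < 0:
        raise ValueError(f"burden index must be non-negative, got {index_value}")
    pos = int(np.searchsorted(np.asarray(partition.boundaries), index_value, side="right"))
    return partition.state_labels[pos]
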