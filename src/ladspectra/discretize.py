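"""Cutpoint discretization: numeric features -> binary threshold features.

For each numeric feature, candidate thresholds ("cutpoints") are the
midpoints between consecutive distinct observed values across which the
class composition changes.  A gap between adjacent distinct values v_a < v_b
yields a cutpoint unless the observations at v_a and at v_b are all of one
and the same class (no class change across the gap); values carrying both
classes generate cutpoints on both sides.  These "essential" cutpoints are
exactly the thresholds that can separate some opposite-class pair, so
binarizing with all of them loses no pairwise separability.

The stored binary feature is the literal ``value >= cutpoint`` (the ``<``
direction is its complement and is never materialized).  Cutpoints are
midpoints of distinct training values, so ties with a cutpoint cannot occur
on the data that produced it; the ``>=`` boundary rule matters only for new
data and is fixed for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .base import ConfigError, LADError
from .preprocess import FeatureMatrix

__all__ = [
    "CutpointSet",
    "BinaryMatrix",
    "find_cutpoints",
    "compute_cutpoints",
    "binarize",
]


def find_cutpoints(values: Sequence[float], labels: Sequence[str]) -> list[float]:
    """Essential cutpoints for one numeric feature.

    Returns midpoints of adjacent distinct sorted values whose attached
    label sets are not both identical singletons.  A feature observed in a
    single class only, or a constant feature, yields no cutpoints.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if values.shape != labels.shape or values.ndim != 1:
        raise ConfigError("values and labels must be 1-D of equal length")
    if not np.all(np.isfinite(values)):
        raise ConfigError("values must be finite")
    if len(set(labels.tolist())) < 2:
        return []
    order = np.argsort(values, kind="stable")
    sv, sl = values[order], labels[order]
    distinct: list[float] = []
    class_sets: list[set] = []
    for v, lab in zip(sv, sl):
        if distinct and v == distinct[-1]:
            class_sets[-1].add(lab)
        else:
            distinct.append(float(v))
            class_sets.append({lab})
    cuts = []
    for a in range(len(distinct) - 1):
        ca, cb = class_sets[a], class_sets[a + 1]
        if len(ca) == 1 and ca == cb:
            continue
        cuts.append((distinct[a] + distinct[a + 1]) / 2.0)
    return cuts


@dataclass
class CutpointSet:
    """Per-feature ascending cutpoint lists, indexed by feature column."""

    cutpoints: dict[int, list[float]]
    n_features: int

    def __post_init__(self) -> None:
        for f, cs in self.cutpoints.items():
            if not 0 <= f < self.n_features:
                raise ConfigError(f"cutpoint feature index {f} out of range "
                                  f"[0, {self.n_features})")
            if any(cs[i] >= cs[i + 1] for i in range(len(cs) - 1)):
                raise ConfigError(f"cutpoints of feature {f} not strictly ascending")

    def features_with_cutpoints(self) -> list[int]:
        return sorted(f for f, cs in self.cutpoints.items() if cs)

    def restrict(self, columns: Sequence[tuple[int, float]]) -> "CutpointSet":
        """Keep only the given (feature, cutpoint) pairs (e.g. a support set)."""
        keep: dict[int, list[float]] = {}
        for f, c in columns:
            keep.setdefault(f, []).append(c)
        return CutpointSet(
            cutpoints={f: sorted(cs) for f, cs in keep.items()},
            n_features=self.n_features,
        )

    @property
    def n_cutpoints(self) -> int:
        return sum(len(cs) for cs in self.cutpoints.values())


def compute_cutpoints(matrix: FeatureMatrix) -> CutpointSet:
    """Essential cutpoints for every feature of a labeled matrix."""
    labels = matrix.label_array()
    cuts = {}
    for f in range(matrix.n_features):
        cs = find_cutpoints(matrix.values[:, f], labels)
        if cs:
            cuts[f] = cs
    return CutpointSet(cutpoints=cuts, n_features=matrix.n_features)


@dataclass
class BinaryMatrix:
    """Patients x binary-feature 0/1 table.

    Column ``k`` is the literal ``source value >= descriptors[k][1]`` on
    feature ``descriptors[k][0]``; the ``< c`` literal is the column's
    complement and is not stored.
    """

    descriptors: list[tuple[int, float]]  # (feature index, cutpoint)
    data: np.ndarray                      # bool, patients x columns
    patient_ids: list[str]
    labels: list[str | None]
    bin_centers: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        n, m = self.data.shape
        if len(self.descriptors) != m:
            raise ConfigError(f"descriptor count {len(self.descriptors)} != columns {m}")
        if len(self.patient_ids) != n or len(self.labels) != n:
            raise ConfigError("patient_ids/labels length mismatch with rows")

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]


def binarize(matrix: FeatureMatrix, cuts: CutpointSet) -> BinaryMatrix:
    """Materialize one ``>=`` column per (feature, cutpoint)."""
    if cuts.n_features != matrix.n_features:
        raise LADError(
            f"cutpoint set built for {cuts.n_features} features, matrix has "
            f"{matrix.n_features}"
        )
    descriptors: list[tuple[int, float]] = []
    cols = []
    for f in sorted(cuts.cutpoints):
        if f >= matrix.n_features:
            raise LADError(f"cutpoint references nonexistent feature {f}")
        for c in cuts.cutpoints[f]:
            descriptors.append((f, float(c)))
            cols.append(matrix.values[:, f] >= c)
    data = (
        np.column_stack(cols) if cols
        else np.zeros((matrix.n_patients, 0), dtype=bool)
    )
    return BinaryMatrix(
        descriptors=descriptors,
        data=data,
        patient_ids=list(matrix.patient_ids),
        labels=list(matrix.labels),
        bin_centers=matrix.bin_centers,
    )
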