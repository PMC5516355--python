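"""Binning, internal-standard normalization and feature-matrix assembly.

Raw centroided spectra are binned into fixed-width m/z intervals (2 Da by
default over [500, 12,000] Da, which yields 5,751 features), normalized to
the spiked insulin internal standard at m/z 5,734.5, and averaged over the
duplicate runs of each patient into one row of a patients x bins feature
matrix.

Bin convention: bin centers sit on the grid ``low, low+width, ..., high``
(both endpoints included) and each bin covers the half-open interval
``[center - width/2, center + width/2)``.  The feature count is therefore
``floor((high - low)/width) + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .base import ConfigError, NormalizationError, LADError
from .synthetic import SpectrumRecord

__all__ = [
    "BinningSpec",
    "FeatureMatrix",
    "bin_spectrum",
    "normalize_to_standard",
    "mass_error_pct",
    "build_feature_matrix",
]

#: Default insulin internal standard mass (Da) and detection window.
DEFAULT_STANDARD_MZ = 5734.5
DEFAULT_STANDARD_WINDOW = 10.0
#: QC bound on the relative mass error of the detected standard, in percent.
MASS_ACCURACY_QC_PCT = 0.06


@dataclass(frozen=True)
class BinningSpec:
    """Fixed-width binning of the m/z axis."""

    low: float = 500.0
    high: float = 12000.0
    width: float = 2.0

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ConfigError(f"low must be < high, got low={self.low} high={self.high}")
        if not self.width > 0:
            raise ConfigError(f"width must be > 0, got {self.width}")

    @property
    def n_features(self) -> int:
        return int(np.floor((self.high - self.low) / self.width)) + 1

    @property
    def bin_centers(self) -> np.ndarray:
        return self.low + self.width * np.arange(self.n_features)


@dataclass
class FeatureMatrix:
    """Patients x binned-m/z intensity table with class labels.

    ``values[i, j]`` is the (normalized) intensity of patient ``i`` in the
    bin centered at ``bin_centers[j]``.
    """

    patient_ids: list[str]
    labels: list[str | None]
    bin_centers: np.ndarray
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if len(self.patient_ids) != n:
            raise ConfigError(f"patient_ids length {len(self.patient_ids)} != row count {n}")
        if len(self.labels) != n:
            raise ConfigError(f"labels length {len(self.labels)} != row count {n}")
        if self.bin_centers.shape != (m,):
            raise ConfigError(f"bin_centers length {self.bin_centers.size} != column count {m}")
        if not np.all(np.isfinite(self.values)):
            raise ConfigError("values must be finite")
        if np.any(self.values < 0):
            raise ConfigError("values must be >= 0")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)

    def subset_rows(self, idx: Sequence[int]) -> "FeatureMatrix":
        idx = np.asarray(idx, dtype=int)
        return FeatureMatrix(
            patient_ids=[self.patient_ids[i] for i in idx],
            labels=[self.labels[i] for i in idx],
            bin_centers=self.bin_centers,
            values=self.values[idx],
            provenance=dict(self.provenance),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"{c:g}" for c in self.bin_centers])
        df.insert(0, "label", self.labels)
        df.insert(0, "patient_id", self.patient_ids)
        return df


def bin_spectrum(record: SpectrumRecord, spec: BinningSpec) -> np.ndarray:
    """Sum peak intensities into fixed-width bins.

    Peaks outside ``[low - width/2, high + width/2)`` are discarded; multiple
    peaks falling into the same bin are summed (total ion intensity within a
    bin is preserved).  The record's peaks must already be sorted by m/z;
    unsorted input raises rather than being silently reordered, to catch
    upstream corruption.
    """
    mz = np.asarray(record.mz, dtype=float)
    if mz.size and np.any(np.diff(mz) <= 0):
        raise LADError(
            f"record {record.patient_id}/{record.replicate_id}: peaks not "
            "strictly sorted by m/z"
        )
    out = np.zeros(spec.n_features)
    if mz.size == 0:
        return out
    idx = np.floor((mz - (spec.low - spec.width / 2)) / spec.width).astype(int)
    ok = (idx >= 0) & (idx < spec.n_features)
    np.add.at(out, idx[ok], np.asarray(record.intensity, dtype=float)[ok])
    return out


def normalize_to_standard(
    vector: np.ndarray,
    bin_centers: np.ndarray,
    standard_mz: float = DEFAULT_STANDARD_MZ,
    window: float = DEFAULT_STANDARD_WINDOW,
    record_id: str = "<unknown>",
) -> tuple[np.ndarray, tuple[float, float]]:
    """Divide a binned vector by the detected internal-standard intensity.

    The standard is detected as the maximum-intensity bin whose center lies
    within ``window`` Da of ``standard_mz`` (ties break toward the lower
    center).  Returns the normalized vector and the detected
    ``(m/z, intensity)`` for QC.
    """
    if window <= 0:
        raise ConfigError(f"window must be > 0, got {window}")
    vector = np.asarray(vector, dtype=float)
    bin_centers = np.asarray(bin_centers, dtype=float)
    near = np.flatnonzero(np.abs(bin_centers - standard_mz) <= window)
    if near.size == 0:
        raise NormalizationError(
            f"record {record_id}: no bin center within {window} Da of "
            f"standard m/z {standard_mz}"
        )
    k = near[int(np.argmax(vector[near]))]
    detected = (float(bin_centers[k]), float(vector[k]))
    if detected[1] <= 0:
        raise NormalizationError(
            f"record {record_id}: detected standard intensity {detected[1]} <= 0 "
            f"at m/z {detected[0]}"
        )
    return vector / detected[1], detected


def mass_error_pct(detected_mz: float, true_mz: float) -> float:
    """Relative mass error of the detected standard, in percent:
    ``100 * |detected - true| / true``."""
    return 100.0 * abs(detected_mz - true_mz) / true_mz


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.array_equal(a, b):
        return 1.0
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def build_feature_matrix(
    records: Sequence[SpectrumRecord],
    spec: BinningSpec | None = None,
    standard_mz: float = DEFAULT_STANDARD_MZ,
    window: float = DEFAULT_STANDARD_WINDOW,
) -> tuple[FeatureMatrix, dict]:
    """Bin, normalize and average replicates into one row per patient.

    Each replicate is binned and normalized independently; the patient's row
    is the arithmetic mean of its normalized replicate vectors.  The QC
    report carries, per patient, the between-replicate Pearson correlation of
    the normalized vectors (computed before averaging) and the detected
    standard's mass error.
    """
    if not records:
        raise ConfigError("records must be non-empty")
    if spec is None:
        spec = BinningSpec()

    order: list[str] = []
    by_patient: dict[str, list[SpectrumRecord]] = {}
    for rec in records:
        if rec.patient_id not in by_patient:
            order.append(rec.patient_id)
            by_patient[rec.patient_id] = []
        by_patient[rec.patient_id].append(rec)

    rows, labels, qc_rows = [], [], []
    for pid in order:
        reps = by_patient[pid]
        rep_labels = {rec.label for rec in reps}
        if len(rep_labels) != 1:
            raise LADError(
                f"patient {pid}: conflicting labels across replicates "
                f"{sorted(map(str, rep_labels))}"
            )
        normed, detections = [], []
        for rec in reps:
            vec = bin_spectrum(rec, spec)
            nv, det = normalize_to_standard(
                vec, spec.bin_centers, standard_mz, window,
                record_id=f"{pid}/{rec.replicate_id}",
            )
            normed.append(nv)
            detections.append(det)
        rs = [
            _pearson(normed[i], normed[j])
            for i in range(len(normed)) for j in range(i + 1, len(normed))
        ]
        mean_vec = np.mean(normed, axis=0)
        rows.append(mean_vec)
        labels.append(reps[0].label)
        errs = [mass_error_pct(d[0], standard_mz) for d in detections]
        qc_rows.append({
            "patient_id": pid,
            "n_replicates": len(reps),
            "replicate_r": float(np.nanmean(rs)) if rs else float("nan"),
            "standard_mz_detected": [d[0] for d in detections],
            "standard_intensity_detected": [d[1] for d in detections],
            "mass_error_pct_max": max(errs),
            "mass_accuracy_ok": max(errs) <= MASS_ACCURACY_QC_PCT,
        })

    matrix = FeatureMatrix(
        patient_ids=order,
        labels=labels,
        bin_centers=spec.bin_centers,
        values=np.vstack(rows),
        provenance={
            "binning": {"low": spec.low, "high": spec.high, "width": spec.width},
            "normalization": {"standard_mz": standard_mz, "window": window},
            "replicate_aggregation": "mean",
        },
    )
    qc = {
        "per_patient": qc_rows,
        "mean_replicate_r": float(np.nanmean([q["replicate_r"] for q in qc_rows])),
        "all_mass_accuracy_ok": all(q["mass_accuracy_ok"] for q in qc_rows),
    }
    return matrix, qc
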