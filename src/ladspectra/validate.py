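"""Repeated stratified k-fold cross-validation of the full training chain.

The cohort is randomly partitioned into k approximately equal parts; each
part in turn is held out while the entire pipeline (cutpoints, degree-1
filter, support set, patterns, model) is refit on the remaining k-1 parts,
and the held-out patients are classified.  The partitioning is re-randomized
``repeats`` times, so k=10 with 10 repeats yields 100 test evaluations.

Metrics follow the usual definitions: accuracy is the proportion of
correctly classified observations, sensitivity the proportion of correctly
classified positive-class (rapid) patients, specificity the proportion of
correctly classified negative-class (slow) patients.  Patients left
unclassified by the discriminant (delta = 0) count as misclassified under
the default policy; an "exclude" policy that drops them from denominators is
available, and unclassified counts are always reported separately.

Because the reported "mean +/- dispersion" can be read either as the spread
over all k*repeats fold evaluations or over the ``repeats`` repeat means,
the report emits both dispersions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .base import POSITIVE_LABEL, NEGATIVE_LABEL, UNCLASSIFIED, ConfigError, LADError
from .preprocess import FeatureMatrix
from .fit import LADPipelineConfig, fit_lad_pipeline

__all__ = ["CVConfig", "CVReport", "make_folds", "metrics", "cross_validate"]


@dataclass(frozen=True)
class CVConfig:
    k: int = 10
    repeats: int = 10
    seed: int = 0
    stratified: bool = True
    unclassified_policy: str = "misclassified"  # or "exclude"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ConfigError(f"k must be >= 2, got {self.k}")
        if self.repeats < 1:
            raise ConfigError(f"repeats must be >= 1, got {self.repeats}")
        if self.unclassified_policy not in ("misclassified", "exclude"):
            raise ConfigError(
                "unclassified_policy must be 'misclassified' or 'exclude', "
                f"got {self.unclassified_policy!r}"
            )

    def to_dict(self) -> dict:
        return asdict(self)


def make_folds(labels, k: int, seed: int, stratified: bool = True) -> np.ndarray:
    """Assign each row a fold index in [0, k).

    Fold sizes differ by at most one overall; under stratification they also
    differ by at most one within each class.  Per-class remainders are dealt
    to the folds with the smallest running totals so both balance laws hold
    simultaneously.  Deterministic in ``seed``.
    """
    labels = np.asarray(labels, dtype=object)
    n = labels.size
    if k > n:
        raise ConfigError(f"k={k} exceeds cohort size {n}")
    rng = np.random.default_rng(seed)
    fold = np.empty(n, dtype=int)
    if not stratified:
        perm = rng.permutation(n)
        for pos, row in enumerate(perm):
            fold[row] = pos % k
        return fold
    classes = sorted(set(labels.tolist()), key=str)
    # larger classes first so their remainders spread before smaller ones
    classes.sort(key=lambda c: -int((labels == c).sum()))
    totals = np.zeros(k, dtype=int)
    for c in classes:
        rows = np.flatnonzero(labels == c)
        rng.shuffle(rows)
        base, rem = divmod(rows.size, k)
        quota = np.full(k, base)
        # remainder goes to folds with smallest current totals (ties: lowest index)
        extra = np.lexsort((np.arange(k), totals))[:rem]
        quota[extra] += 1
        start = 0
        for f in range(k):
            fold[rows[start:start + quota[f]]] = f
            start += quota[f]
        totals += quota
    return fold


def metrics(predictions, labels, unclassified_policy: str = "misclassified") -> dict:
    """Accuracy / sensitivity / specificity of class calls against labels.

    ``predictions`` entries are POSITIVE_LABEL, NEGATIVE_LABEL or
    UNCLASSIFIED.  Returns a dict with the three proportions plus
    ``n_unclassified`` and the counts behind each denominator.
    """
    predictions = list(predictions)
    labels = list(labels)
    if not predictions or len(predictions) != len(labels):
        raise ConfigError("predictions and labels must be non-empty and aligned")
    rows = list(zip(predictions, labels))
    if unclassified_policy == "exclude":
        scored = [(p, l) for p, l in rows if p != UNCLASSIFIED]
    else:
        scored = rows
    n_unc = sum(p == UNCLASSIFIED for p, _ in rows)

    def _prop(pairs):
        if not pairs:
            return float("nan")
        return sum(p == l for p, l in pairs) / len(pairs)

    pos = [(p, l) for p, l in scored if l == POSITIVE_LABEL]
    neg = [(p, l) for p, l in scored if l == NEGATIVE_LABEL]
    return {
        "accuracy": _prop(scored),
        "sensitivity": _prop(pos),
        "specificity": _prop(neg),
        "n_unclassified": n_unc,
        "n_scored": len(scored),
        "n_positive": len(pos),
        "n_negative": len(neg),
    }


@dataclass
class CVReport:
    """Per-test records and aggregate statistics of a repeated k-fold run."""

    records: pd.DataFrame
    config: CVConfig
    aggregates: dict = field(default_factory=dict)

    @property
    def n_tests(self) -> int:
        return len(self.records)

    @property
    def n_failed(self) -> int:
        return int(self.records["failed"].sum())


def _aggregate(records: pd.DataFrame) -> dict:
    ok = records[~records["failed"]]
    agg: dict = {"n_tests": len(records), "n_failed": int(records["failed"].sum())}
    for m in ("accuracy", "sensitivity", "specificity"):
        vals = ok[m].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        agg[m] = {
            "mean": float(vals.mean()) if vals.size else float("nan"),
            "sd_over_tests": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
        }
        by_rep = ok.groupby("repeat")[m].mean().to_numpy(dtype=float)
        by_rep = by_rep[~np.isnan(by_rep)]
        agg[m]["sd_over_repeat_means"] = (
            float(by_rep.std(ddof=1)) if by_rep.size > 1 else float("nan")
        )
    agg["total_unclassified"] = int(ok["n_unclassified"].sum())
    return agg


def cross_validate(
    matrix: FeatureMatrix,
    pipeline_config: LADPipelineConfig | None = None,
    cv: CVConfig | None = None,
) -> CVReport:
    """Repeated stratified k-fold CV with per-split refitting.

    Every training-stage quantity (cutpoints, retained features, support
    set, patterns, model) is recomputed from the training split alone.  A
    split on which training fails (e.g. a class missing) is recorded as a
    failed test with NaN metrics and surfaced in the report, never silently
    dropped.
    """
    if cv is None:
        cv = CVConfig()
    if pipeline_config is None:
        pipeline_config = LADPipelineConfig()
    labels = matrix.label_array()
    rec_rows = []
    for rep in range(cv.repeats):
        fold = make_folds(labels, cv.k, seed=cv.seed + rep, stratified=cv.stratified)
        for f in range(cv.k):
            test_idx = np.flatnonzero(fold == f)
            train_idx = np.flatnonzero(fold != f)
            row = {
                "repeat": rep, "fold": f,
                "n_test": int(test_idx.size),
                "test_ids": ";".join(matrix.patient_ids[i] for i in test_idx),
            }
            try:
                fitted = fit_lad_pipeline(matrix.subset_rows(train_idx), pipeline_config)
                preds = [fitted.predict(matrix.values[i]).predicted for i in test_idx]
                m = metrics(preds, [labels[i] for i in test_idx],
                            unclassified_policy=cv.unclassified_policy)
                row.update(
                    accuracy=m["accuracy"], sensitivity=m["sensitivity"],
                    specificity=m["specificity"],
                    n_unclassified=m["n_unclassified"],
                    failed=False, error="",
                )
            except LADError as exc:
                row.update(
                    accuracy=float("nan"), sensitivity=float("nan"),
                    specificity=float("nan"), n_unclassified=0,
                    failed=True, error=str(exc),
                )
            rec_rows.append(row)
    records = pd.DataFrame(rec_rows)
    return CVReport(records=records, config=cv, aggregates=_aggregate(records))
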