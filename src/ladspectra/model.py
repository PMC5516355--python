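"""Model assembly, the LAD discriminant, risk stratification and ROC/AUC.

The classifier is a collection of P positive and N negative patterns.  For
a patient covered by p positive and n negative patterns the discriminant is

    delta = p/P - n/N  in [-1, 1],

positive delta predicting the positive (rapid) class, negative delta the
negative (slow) class, and delta = 0 leaving the patient unclassified.  The
risk score r = (delta + 1)/2 rescales the discriminant to [0, 1] for
quantile risk stratification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, norm

from .base import (
    POSITIVE_LABEL,
    SIGN_POSITIVE,
    SIGN_NEGATIVE,
    UNCLASSIFIED,
    ConfigError,
    InfeasibleError,
    LADError,
)
from .preprocess import FeatureMatrix
from .patterns import Pattern, pattern_covers

__all__ = [
    "LADModel",
    "DiscriminantResult",
    "RiskGroupTable",
    "AUCResult",
    "select_model",
    "discriminant",
    "predict_matrix",
    "risk_groups",
    "roc_auc",
]


@dataclass
class LADModel:
    """P positive + N negative patterns plus training metadata."""

    positive_patterns: list[Pattern]
    negative_patterns: list[Pattern]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.positive_patterns or not self.negative_patterns:
            raise ConfigError(
                "a model needs at least one pattern of each sign "
                f"(got P={len(self.positive_patterns)}, N={len(self.negative_patterns)})"
            )
        for p in self.positive_patterns:
            if p.sign != SIGN_POSITIVE:
                raise ConfigError("positive_patterns contains a negative-sign pattern")
        for p in self.negative_patterns:
            if p.sign != SIGN_NEGATIVE:
                raise ConfigError("negative_patterns contains a positive-sign pattern")

    @property
    def P(self) -> int:
        return len(self.positive_patterns)

    @property
    def N(self) -> int:
        return len(self.negative_patterns)

    @property
    def features_used(self) -> list[int]:
        return sorted({
            l.feature
            for p in self.positive_patterns + self.negative_patterns
            for l in p.literals
        })


@dataclass(frozen=True)
class DiscriminantResult:
    """Per-patient pattern counts, discriminant, risk score and call."""

    p: int
    n: int
    P: int
    N: int
    delta_fraction: Fraction
    predicted: str  # POSITIVE_LABEL, NEGATIVE_LABEL or UNCLASSIFIED

    @property
    def delta(self) -> float:
        return float(self.delta_fraction)

    @property
    def risk(self) -> float:
        return float((self.delta_fraction + 1) / 2)


def _greedy_sign_cover(
    candidates: list[Pattern], own_rows: np.ndarray, patient_ids: list[str],
    multiplicity: int = 1,
) -> list[Pattern]:
    """Greedy cover of own-class rows by same-sign patterns.

    With ``multiplicity`` = 1 this is plain greedy minimum set cover with a
    reverse-selection-order irredundancy prune.  With m > 1 it is greedy
    multicover: each own-class row must be covered by min(m, number of
    candidates covering it) patterns, and candidates introducing a feature
    set not yet in the model are preferred — redundant, feature-diverse
    coverage makes the pattern-count discriminant graded instead of
    three-valued, which matters for patients near the class boundary.

    Tie chain after the diversity preference: most outstanding coverage
    demand met, then higher homogeneity, then higher prevalence, then
    lexicographically smallest literal tuple.
    """
    own_set = set(np.flatnonzero(own_rows).tolist())
    cover_count: dict[int, int] = {i: 0 for i in own_set}
    for q in candidates:
        for i in q.covered & own_set:
            cover_count[i] += 1
    uncoverable = [i for i in own_set if cover_count[i] == 0]
    if uncoverable:
        names = sorted(patient_ids[i] for i in uncoverable)
        raise InfeasibleError(
            f"own-class patients coverable by no candidate pattern: {names}"
        )
    need = {i: min(multiplicity, cover_count[i]) for i in own_set}

    selected: list[Pattern] = []
    pool = list(candidates)
    feature_sets: set[frozenset[int]] = set()
    while any(v > 0 for v in need.values()):
        best, best_key = None, None
        for q in pool:
            gain = sum(1 for i in q.covered & own_set if need[i] > 0)
            if gain == 0:
                continue
            fs = frozenset(l.feature for l in q.literals)
            key = (fs in feature_sets, -gain, -q.homogeneity, -q.prevalence,
                   q.sort_key())
            if best_key is None or key < best_key:
                best, best_key = q, key
        assert best is not None  # uncoverable rows were checked above
        selected.append(best)
        pool.remove(best)
        feature_sets.add(frozenset(l.feature for l in best.literals))
        for i in best.covered & own_set:
            if need[i] > 0:
                need[i] -= 1

    target = {i: min(multiplicity, cover_count[i]) for i in own_set}
    kept = list(selected)
    for q in reversed(selected):
        counts = {i: 0 for i in own_set}
        for s in kept:
            if s is q:
                continue
            for i in s.covered & own_set:
                counts[i] += 1
        if all(counts[i] >= target[i] for i in own_set):
            kept.remove(q)
    return kept


def select_model(
    candidates: Sequence[Pattern], matrix: FeatureMatrix, multiplicity: int = 1
) -> LADModel:
    """Assemble the final model as a per-sign greedy pattern cover.

    Every training patient must end up covered by at least one pattern of
    its own sign (coverage completeness); an uncoverable patient raises
    :class:`InfeasibleError` naming it.  ``multiplicity`` > 1 requests
    redundant coverage (see :func:`_greedy_sign_cover`); the default is the
    plain greedy minimum cover.
    """
    pos_cands = [c for c in candidates if c.sign == SIGN_POSITIVE]
    neg_cands = [c for c in candidates if c.sign == SIGN_NEGATIVE]
    labels = matrix.label_array()
    pos_model = _greedy_sign_cover(pos_cands, labels == POSITIVE_LABEL,
                                   matrix.patient_ids, multiplicity)
    neg_model = _greedy_sign_cover(neg_cands, labels != POSITIVE_LABEL,
                                   matrix.patient_ids, multiplicity)
    model = LADModel(
        positive_patterns=pos_model,
        negative_patterns=neg_model,
        meta={"n_candidates": len(candidates)},
    )
    # coverage completeness (model invariant) re-checked on the full model
    for sign_patterns, own in (
        (model.positive_patterns, labels == POSITIVE_LABEL),
        (model.negative_patterns, labels != POSITIVE_LABEL),
    ):
        covered = set().union(*[p.covered for p in sign_patterns])
        missing = set(np.flatnonzero(own).tolist()) - covered
        if missing:
            raise InfeasibleError(
                f"model coverage incomplete for rows {sorted(missing)}"
            )
    return model


def exhaustive_sign_cover_size(candidates: list[Pattern], own_rows: set[int],
                               max_subset: int = 20) -> int:
    """Smallest number of same-sign candidates covering all own rows
    (brute-force oracle for tests)."""
    if len(candidates) > max_subset:
        raise LADError(f"oracle guarded to <= {max_subset} candidates")
    for size in range(1, len(candidates) + 1):
        for subset in combinations(candidates, size):
            if own_rows <= set().union(*[p.covered for p in subset]):
                return size
    raise InfeasibleError("no candidate subset covers all own-class rows")


def discriminant(model: LADModel, vector: np.ndarray) -> DiscriminantResult:
    """Exact rational discriminant of one patient under a model."""
    vector = np.asarray(vector, dtype=float)
    p = sum(pattern_covers(q, vector) for q in model.positive_patterns)
    n = sum(pattern_covers(q, vector) for q in model.negative_patterns)
    delta = Fraction(p, model.P) - Fraction(n, model.N)
    if delta > 0:
        pred = POSITIVE_LABEL
    elif delta < 0:
        from .base import NEGATIVE_LABEL
        pred = NEGATIVE_LABEL
    else:
        pred = UNCLASSIFIED
    return DiscriminantResult(p=p, n=n, P=model.P, N=model.N,
                              delta_fraction=delta, predicted=pred)


def predict_matrix(model: LADModel, matrix: FeatureMatrix) -> list[DiscriminantResult]:
    return [discriminant(model, matrix.values[i]) for i in range(matrix.n_patients)]


@dataclass
class RiskGroupTable:
    """Quantile risk groups ordered from lowest (1) to highest (g) score."""

    table: pd.DataFrame  # group, n, pct_positive, mean_risk, min_risk, max_risk
    g: int
    assignments: pd.DataFrame  # patient_id, risk, group


def risk_groups(
    results: Sequence[DiscriminantResult],
    labels: Sequence[str | None],
    patient_ids: Sequence[str],
    g: int = 5,
) -> RiskGroupTable:
    """Split patients into ``g`` contiguous near-equal groups by risk score.

    Patients are ordered by (risk score, patient id) ascending; the
    ``cohort % g`` remainder patients go to the highest-score groups, so 116
    patients in quintiles give group sizes 23/23/23/23/24.  ``pct_positive``
    is the percentage of positive-class patients per group (0-100 scale).
    """
    n = len(results)
    if g < 2:
        raise ConfigError(f"g must be >= 2, got {g}")
    if n < g:
        raise ConfigError(f"cohort size {n} smaller than group count {g}")
    if not (len(labels) == len(patient_ids) == n):
        raise ConfigError("results, labels and patient_ids must align")
    order = sorted(range(n), key=lambda i: (results[i].risk, patient_ids[i]))
    base, rem = divmod(n, g)
    sizes = [base] * (g - rem) + [base + 1] * rem
    rows, assign_rows = [], []
    start = 0
    for gi, size in enumerate(sizes, start=1):
        idx = order[start:start + size]
        start += size
        risks = [results[i].risk for i in idx]
        pos = sum(labels[i] == POSITIVE_LABEL for i in idx)
        rows.append({
            "group": gi,
            "n": size,
            "pct_positive": 100.0 * pos / size,
            "mean_risk": float(np.mean(risks)),
            "min_risk": float(min(risks)),
            "max_risk": float(max(risks)),
        })
        for i in idx:
            assign_rows.append({"patient_id": patient_ids[i],
                                "risk": results[i].risk, "group": gi})
    return RiskGroupTable(table=pd.DataFrame(rows), g=g,
                          assignments=pd.DataFrame(assign_rows))


@dataclass(frozen=True)
class AUCResult:
    auc: float
    ci_low: float
    ci_high: float
    method: str
    n_positive: int
    n_negative: int


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[str],
    positive_label: str = POSITIVE_LABEL,
    ci: str = "hanley-mcneil",
    confidence: float = 0.95,
    n_boot: int = 2000,
    seed: int | None = None,
) -> AUCResult:
    """AUC as the Mann-Whitney probability (ties count 1/2) with a CI.

    ``ci`` is ``"hanley-mcneil"`` (normal approximation on the Hanley &
    McNeil variance) or ``"bootstrap"`` (seeded patient resampling,
    percentile interval).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    pos = labels == positive_label
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise LADError(f"roc_auc needs both classes (got {n1} positive, {n0} negative)")
    ranks = rankdata(scores)  # midranks: ties counted 1/2
    auc = (ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    z = norm.ppf(0.5 + confidence / 2)
    if ci == "hanley-mcneil":
        a = auc
        q1 = a / (2 - a)
        q2 = 2 * a * a / (1 + a)
        var = (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n0 - 1) * (q2 - a * a)) / (n1 * n0)
        se = float(np.sqrt(max(var, 0.0)))
        lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    elif ci == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = np.arange(scores.size)
        boots = []
        while len(boots) < n_boot:
            samp = rng.choice(idx, size=idx.size, replace=True)
            sp = pos[samp]
            if sp.all() or not sp.any():
                continue
            rs = rankdata(scores[samp])
            b1, b0 = int(sp.sum()), int((~sp).sum())
            boots.append((rs[sp].sum() - b1 * (b1 + 1) / 2) / (b1 * b0))
        alpha = (1 - confidence) / 2
        lo, hi = np.quantile(boots, [alpha, 1 - alpha])
    else:
        raise ConfigError(f"unknown ci method {ci!r}")
    return AUCResult(auc=float(auc), ci_low=float(lo), ci_high=float(hi),
                     method=ci, n_positive=n1, n_negative=n0)
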