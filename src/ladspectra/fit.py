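"""End-to-end LAD training on a labeled feature matrix.

Chains the method's stages on one training set: essential cutpoints ->
degree-1 feature filter -> binarization -> support-set selection -> bounded-
degree pattern enumeration -> greedy model assembly.  Cross-validation
refits this whole chain on every training split, so no information from
held-out patients leaks into cutpoints, filters, support sets or patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from itertools import combinations, product
from typing import Sequence

import numpy as np

from .base import SIGN_POSITIVE, SIGN_NEGATIVE, ConfigError, InfeasibleError
from .preprocess import FeatureMatrix
from .discretize import CutpointSet, compute_cutpoints, binarize
from .support import SupportSet, greedy_support_set, exhaustive_support_set
from .patterns import (
    Literal, Pattern, GE, LT, enumerate_patterns, degree1_feature_filter,
    pattern_stats,
)
from .model import LADModel, DiscriminantResult, select_model, discriminant

__all__ = ["LADPipelineConfig", "FittedLAD", "fit_lad_pipeline"]


@dataclass(frozen=True)
class LADPipelineConfig:
    """Tunable parameters of the training chain.

    The degree-1 screen uses the strict 80%/80% prevalence-homogeneity
    thresholds; the degree-2 candidate stage must admit lower prevalence
    (final two-feature patterns typically cover ~57-58% of their class), so
    its defaults are looser.
    """

    filter_min_homogeneity: float = 0.8
    filter_min_prevalence: float = 0.8
    candidate_min_homogeneity: float = 0.75
    candidate_min_prevalence: float = 0.3
    max_degree: int = 2
    support_mode: str = "greedy"          # "greedy" | "exact"
    apply_degree1_filter: bool = True
    #: When the degree-1 screen retains nothing (e.g. label-permuted data),
    #: fall back to all features rather than failing the whole fit.
    fallback_to_all_features: bool = True
    #: Augment candidates so every training patient is coverable (see
    #: _coverage_completion); keeps model assembly feasible.
    ensure_coverage: bool = True
    dominance_prune: bool = True
    #: Redundant-coverage depth of the final model: each training patient is
    #: covered by up to this many own-sign patterns (capped by what the
    #: candidate pool offers).  1 = plain minimum cover; 3 gives a graded
    #: discriminant like the multi-pattern models the method is known for.
    model_cover_multiplicity: int = 3

    def __post_init__(self) -> None:
        for name in ("filter_min_homogeneity", "filter_min_prevalence",
                     "candidate_min_homogeneity", "candidate_min_prevalence"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.max_degree < 1:
            raise ConfigError(f"max_degree must be >= 1, got {self.max_degree}")
        if self.support_mode not in ("greedy", "exact"):
            raise ConfigError(f"support_mode must be 'greedy' or 'exact', "
                              f"got {self.support_mode!r}")
        if self.model_cover_multiplicity < 1:
            raise ConfigError(
                f"model_cover_multiplicity must be >= 1, got "
                f"{self.model_cover_multiplicity}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LADPipelineConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown LADPipelineConfig keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class FittedLAD:
    """Everything a training run produced, ready to predict new patients."""

    config: LADPipelineConfig
    cuts: CutpointSet
    retained_features: list[int]
    support_set: SupportSet
    candidates: list[Pattern]
    model: LADModel
    bin_centers: np.ndarray

    def predict(self, vector: np.ndarray) -> DiscriminantResult:
        return discriminant(self.model, vector)

    def predict_many(self, values: np.ndarray) -> list[DiscriminantResult]:
        return [discriminant(self.model, v) for v in np.asarray(values, dtype=float)]


def _coverage_completion(
    matrix: FeatureMatrix,
    support_cuts: CutpointSet,
    candidates: list[Pattern],
    sign: str,
    max_degree: int,
) -> list[Pattern]:
    """Patterns added so every own-class patient is covered by some same-sign
    candidate.

    For each still-uncovered own-class patient, consider every literal
    combination (within the support literal space, degree <= max_degree)
    that covers the patient, and keep the one with the best (homogeneity,
    prevalence, literal order).  Such a combination always exists: the
    degree-1 literal matching the patient's side of any support column.
    """
    from .base import SIGN_TO_LABEL
    labels = matrix.label_array()
    own_rows = set(np.flatnonzero(labels == SIGN_TO_LABEL[sign]).tolist())
    covered = set().union(*[p.covered for p in candidates]) if candidates else set()
    missing = sorted(own_rows - covered)
    if not missing:
        return []
    feats = sorted(support_cuts.cutpoints)
    added: list[Pattern] = []
    for row in missing:
        vec = matrix.values[row]
        best = None
        for degree in range(1, max_degree + 1):
            for combo in combinations(feats, degree):
                lit_options = []
                for f in combo:
                    opts = []
                    for c in support_cuts.cutpoints[f]:
                        d = GE if vec[f] >= c else LT
                        opts.append(Literal(f, c, d))
                    lit_options.append(opts)
                for lits in product(*lit_options):
                    p = pattern_stats(lits, sign, matrix)
                    if p is None or row not in p.covered:
                        continue
                    key = (-p.homogeneity, -p.prevalence, p.sort_key())
                    if best is None or key < best[0]:
                        best = (key, p)
        if best is None:
            raise InfeasibleError(
                f"patient {matrix.patient_ids[row]} coverable by no pattern "
                "in the support literal space"
            )
        added.append(best[1])
        covered |= best[1].covered
    return added


def fit_lad_pipeline(
    matrix: FeatureMatrix, config: LADPipelineConfig | None = None
) -> FittedLAD:
    """Run the full training chain on a labeled matrix."""
    if config is None:
        config = LADPipelineConfig()
    cuts = compute_cutpoints(matrix)

    if config.apply_degree1_filter:
        retained = degree1_feature_filter(
            matrix, cuts,
            min_homogeneity=config.filter_min_homogeneity,
            min_prevalence=config.filter_min_prevalence,
        )
        if not retained and config.fallback_to_all_features:
            retained = cuts.features_with_cutpoints()
    else:
        retained = cuts.features_with_cutpoints()
    if not retained:
        raise InfeasibleError("no feature has any essential cutpoint")

    restricted = CutpointSet(
        cutpoints={f: cuts.cutpoints[f] for f in retained if f in cuts.cutpoints},
        n_features=cuts.n_features,
    )
    bin_matrix = binarize(matrix, restricted)
    if config.support_mode == "exact":
        support = exhaustive_support_set(bin_matrix)
    else:
        support = greedy_support_set(bin_matrix)

    support_cuts = cuts.restrict(support.descriptors)
    candidates: list[Pattern] = []
    for sign in (SIGN_POSITIVE, SIGN_NEGATIVE):
        candidates.extend(
            enumerate_patterns(
                matrix, support_cuts,
                features_allowed=sorted(support_cuts.cutpoints),
                sign=sign,
                max_degree=config.max_degree,
                min_homogeneity=config.candidate_min_homogeneity,
                min_prevalence=config.candidate_min_prevalence,
                dominance_prune=config.dominance_prune,
            )
        )
        if config.ensure_coverage:
            candidates.extend(
                _coverage_completion(matrix, support_cuts,
                                     [c for c in candidates if c.sign == sign],
                                     sign, config.max_degree)
            )

    model = select_model(candidates, matrix,
                         multiplicity=config.model_cover_multiplicity)
    return FittedLAD(
        config=config,
        cuts=cuts,
        retained_features=retained,
        support_set=support,
        candidates=candidates,
        model=model,
        bin_centers=matrix.bin_centers,
    )
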