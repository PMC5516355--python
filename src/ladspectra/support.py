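"""Support-set selection: a small irredundant set of binary features that
distinguishes every (positive, negative) patient pair.

The universe is the set of opposite-class pairs; a binary column covers the
pairs on which its two members disagree.  The production solver is greedy
set cover (pick the column covering the most uncovered pairs, lowest column
index on ties) followed by an irredundancy prune in reverse selection order.
An exhaustive minimum-cardinality solver is provided as a test oracle and is
guarded to small instances.

Pair coverage is held in Python integer bitmasks (one bit per pair), which
keeps the 57 x 59 = 3,363-pair cohort cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .base import POSITIVE_LABEL, NEGATIVE_LABEL, InfeasibleError, GuardError
from .discretize import BinaryMatrix

__all__ = ["SupportSet", "greedy_support_set", "exhaustive_support_set"]

EXHAUSTIVE_COLUMN_GUARD = 25


@dataclass
class SupportSet:
    """Selected binary features plus solver metadata."""

    column_indices: list[int]              # into BinaryMatrix columns
    descriptors: list[tuple[int, float]]   # (source feature, cutpoint)
    method: str                            # "greedy" | "exhaustive"
    meta: dict = field(default_factory=dict)

    @property
    def source_features(self) -> list[int]:
        return sorted({f for f, _ in self.descriptors})

    def __len__(self) -> int:
        return len(self.column_indices)


def _pair_masks(bin: BinaryMatrix) -> tuple[list[int], int, list[tuple[str, str]]]:
    """Per-column coverage bitmasks over the opposite-class pair universe.

    Returns (masks, full_mask, pair_ids) where bit ``i*n_neg + j`` stands for
    the pair (positive patient i, negative patient j).
    """
    labels = np.asarray(bin.labels, dtype=object)
    pos = np.flatnonzero(labels == POSITIVE_LABEL)
    neg = np.flatnonzero(labels == NEGATIVE_LABEL)
    if pos.size == 0 or neg.size == 0:
        raise InfeasibleError(
            f"support set needs both classes; got {pos.size} positive and "
            f"{neg.size} negative patients"
        )
    n_pairs = pos.size * neg.size
    full = (1 << n_pairs) - 1
    pair_ids = [
        (bin.patient_ids[i], bin.patient_ids[j]) for i in pos for j in neg
    ]
    masks: list[int] = []
    P = bin.data[pos]  # n_pos x m
    N = bin.data[neg]  # n_neg x m
    for k in range(bin.n_columns):
        diff = P[:, k][:, None] != N[None, :, k]  # n_pos x n_neg
        bits = np.packbits(diff.reshape(-1), bitorder="little")
        masks.append(int.from_bytes(bits.tobytes(), "little"))
    return masks, full, pair_ids


def _check_feasible(masks: list[int], full: int,
                    pair_ids: list[tuple[str, str]]) -> None:
    union = 0
    for m in masks:
        union |= m
        if union == full:
            return
    missing = full & ~union
    bad = []
    i = 0
    while missing and len(bad) < 10:
        if missing & 1:
            bad.append(pair_ids[i])
        missing >>= 1
        i += 1
    raise InfeasibleError(
        "no binary feature distinguishes these opposite-class pairs "
        f"(first {len(bad)} shown): {bad}"
    )


def _is_irredundant(selected: list[int], masks: list[int], full: int) -> bool:
    for drop in range(len(selected)):
        union = 0
        for i, k in enumerate(selected):
            if i != drop:
                union |= masks[k]
        if union == full:
            return False
    return True


def greedy_support_set(bin: BinaryMatrix) -> SupportSet:
    """Greedy set cover over opposite-class pairs, then reverse-order prune.

    Deterministic: ties in coverage gain break toward the lowest column
    index.  Raises :class:`InfeasibleError`, listing offending pairs, when
    some opposite-class pair is identical on every column.
    """
    masks, full, pair_ids = _pair_masks(bin)
    _check_feasible(masks, full, pair_ids)

    uncovered = full
    selected: list[int] = []
    trace: list[dict] = []
    remaining = set(range(len(masks)))
    while uncovered:
        best_k, best_gain = -1, 0
        for k in sorted(remaining):
            gain = (masks[k] & uncovered).bit_count()
            if gain > best_gain:
                best_k, best_gain = k, gain
        # feasibility already checked, so a positive-gain column exists
        selected.append(best_k)
        remaining.discard(best_k)
        trace.append({"column": best_k, "gain": best_gain})
        uncovered &= ~masks[best_k]

    # prune in reverse selection order
    kept = list(selected)
    for k in reversed(selected):
        others = 0
        for j in kept:
            if j != k:
                others |= masks[j]
        if others == full:
            kept.remove(k)
    kept.sort()
    assert _is_irredundant(kept, masks, full)
    return SupportSet(
        column_indices=kept,
        descriptors=[bin.descriptors[k] for k in kept],
        method="greedy",
        meta={"trace": trace, "n_pairs": full.bit_count()},
    )


def exhaustive_support_set(
    bin: BinaryMatrix, max_columns: int = EXHAUSTIVE_COLUMN_GUARD
) -> SupportSet:
    """Minimum-cardinality support set by subset enumeration (test oracle).

    Enumerates column subsets in order of increasing size and returns the
    first that covers every opposite-class pair; a minimum-size cover is
    automatically irredundant.  Refuses instances with more than
    ``max_columns`` columns — use :func:`greedy_support_set` there.
    """
    if bin.n_columns > max_columns:
        raise GuardError(
            f"exhaustive solver guarded to <= {max_columns} columns, got "
            f"{bin.n_columns}; use greedy_support_set"
        )
    masks, full, pair_ids = _pair_masks(bin)
    _check_feasible(masks, full, pair_ids)
    # drop all-zero columns from the search; keep original indices
    useful = [k for k in range(len(masks)) if masks[k]]
    for size in range(1, len(useful) + 1):
        for subset in combinations(useful, size):
            union = 0
            for k in subset:
                union |= masks[k]
            if union == full:
                kept = sorted(subset)
                return SupportSet(
                    column_indices=kept,
                    descriptors=[bin.descriptors[k] for k in kept],
                    method="exhaustive",
                    meta={"certificate": "minimum cardinality by enumeration",
                          "n_pairs": full.bit_count()},
                )
    raise AssertionError("unreachable: feasibility was checked")
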