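"""CASP-convention scoring of predicted contact maps against native structure.

A residue pair is a true contact when its native Cbeta-Cbeta distance is
strictly below 8.0 A. Pairs are binned by sequence separation |i - j|:
short range 6-11, medium 12-23, long >= 24 residues. Within a band,
predictions are ranked by probability and the standard statistics are:

* precision at top L/k — the fraction of correct contacts among the
  floor(L/k) highest-probability pairs (L = sequence length);
* coverage — 100 * TP / N with N the number of native contacts in the band;
* ROC AUC over all assessable pairs in the band;
* the mean native distance of the false positives among the top-k pairs.

Pairs with a missing native distance are unassessable and are excluded from
ranking (not counted as wrong), the CASP assessor convention. Tie-breaking
in the ranking is fully deterministic — probability descending, then
separation descending, then (i, j) ascending — because top-k precision is
sensitive to order at equal scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .maps import CONTACT_THRESHOLD, ContactMap, DistanceMatrix
from .msa import DomainSegment


@dataclass(frozen=True)
class RangeClass:
    """A sequence-separation band: min_sep <= |i - j| <= max_sep."""

    name: str
    min_sep: int
    max_sep: int | None  # None = unbounded

    def contains(self, separation: int | np.ndarray):
        upper = True if self.max_sep is None else separation <= self.max_sep
        return (separation >= self.min_sep) & upper


SHORT_RANGE = RangeClass("short", 6, 11)
MEDIUM_RANGE = RangeClass("medium", 12, 23)
LONG_RANGE = RangeClass("long", 24, None)
RANGES = {"short": SHORT_RANGE, "medium": MEDIUM_RANGE, "long": LONG_RANGE}

STANDARD_FRACTIONS = {"L/10": 0.1, "L/5": 0.2, "L/2": 0.5, "L": 1.0, "2L": 2.0}


def rank_pairs(
    cmap: ContactMap, range_class: RangeClass = LONG_RANGE
) -> list[tuple[int, int, float]]:
    """Pairs (i < j, 1-based) in the band, sorted by probability descending.

    Ties broken by separation descending, then (i, j) ascending, so the
    ordering is deterministic.
    """
    L = cmap.L
    iu, ju = np.triu_indices(L, k=1)
    sep = ju - iu
    keep = range_class.contains(sep)
    iu, ju = iu[keep], ju[keep]
    probs = cmap.prob[iu, ju]
    seps = ju - iu
    order = sorted(
        range(len(iu)), key=lambda t: (-probs[t], -seps[t], iu[t], ju[t])
    )
    return [(int(iu[t]) + 1, int(ju[t]) + 1, float(probs[t])) for t in order]


def _assessable(native: DistanceMatrix, i1: int, j1: int) -> bool:
    return not math.isnan(native.dist[i1 - 1, j1 - 1])


def _is_contact(native: DistanceMatrix, i1: int, j1: int, threshold: float) -> bool:
    return native.dist[i1 - 1, j1 - 1] < threshold


def top_k(fraction: float, L: int) -> int:
    """k = floor(L * fraction), minimum 1."""
    return max(1, math.floor(L * fraction))


def precision_topk(
    pred: ContactMap,
    native: DistanceMatrix,
    fraction: float = 0.2,
    range_class: RangeClass = LONG_RANGE,
    k: int | None = None,
    contact_threshold: float = CONTACT_THRESHOLD,
    one_per_residue: bool = False,
    include_zero_prob: bool = False,
) -> float | None:
    """Percentage of true contacts among the top-k ranked assessable pairs.

    ``k`` defaults to floor(L * fraction), minimum 1. Unassessable pairs are
    skipped and replaced by the next-ranked ones. Following assessor
    practice, only pairs actually predicted (probability > 0) are assessed —
    a map lists only its confident pairs — so the denominator is
    min(k, number of predicted pairs); pass ``include_zero_prob=True`` to
    rank the whole band instead. Returns None when nothing is assessable.
    """
    if pred.L != native.L:
        raise ValueError("prediction and native sizes differ")
    if k is None:
        k = top_k(fraction, pred.L)
    ranked = [
        p
        for p in rank_pairs(pred, range_class)
        if _assessable(native, p[0], p[1]) and (include_zero_prob or p[2] > 0)
    ]
    if one_per_residue:
        ranked = one_per_residue_filter(ranked)
    taken = ranked[:k]
    if not taken:
        return None
    tp = sum(_is_contact(native, i, j, contact_threshold) for i, j, _ in taken)
    return 100.0 * tp / len(taken)


def coverage_stat(
    pred: ContactMap,
    native: DistanceMatrix,
    k: int,
    range_class: RangeClass = LONG_RANGE,
    contact_threshold: float = CONTACT_THRESHOLD,
) -> float | None:
    """Coverage = 100 * TP / N over the top-k list, N = native contacts in band.

    Non-decreasing in k. Returns None when the band has no native contact.
    """
    if pred.L != native.L:
        raise ValueError("prediction and native sizes differ")
    ranked = [
        p for p in rank_pairs(pred, range_class) if _assessable(native, p[0], p[1])
    ]
    n_native = sum(_is_contact(native, i, j, contact_threshold) for i, j, _ in ranked)
    if n_native == 0:
        return None
    if k <= 0:
        return 0.0
    predicted = [p for p in ranked if p[2] > 0]
    tp = sum(
        _is_contact(native, i, j, contact_threshold) for i, j, _ in predicted[:k]
    )
    return 100.0 * tp / n_native


def roc_auc(
    pred: ContactMap,
    native: DistanceMatrix,
    range_class: RangeClass = LONG_RANGE,
    contact_threshold: float = CONTACT_THRESHOLD,
) -> float | None:
    """AUC of probability scores against binary native labels over all
    assessable pairs in the band (mid-rank tie convention). None when the
    band lacks a positive or a negative pair."""
    if pred.L != native.L:
        raise ValueError("prediction and native sizes differ")
    pairs = [
        p for p in rank_pairs(pred, range_class) if _assessable(native, p[0], p[1])
    ]
    if not pairs:
        return None
    labels = np.array(
        [_is_contact(native, i, j, contact_threshold) for i, j, _ in pairs], dtype=int
    )
    scores = np.array([p for _, _, p in pairs])
    if labels.min() == labels.max():
        return None
    return float(roc_auc_score(labels, scores))


def mean_fp_distance(
    pred: ContactMap,
    native: DistanceMatrix,
    k: int | None = None,
    range_class: RangeClass = LONG_RANGE,
    contact_threshold: float = CONTACT_THRESHOLD,
) -> float | None:
    """Mean native distance (A) of the false positives among the top-k pairs.

    A small value means the wrong predictions are at least geometrically
    close to being right. ``k`` defaults to floor(L/5). None when the top-k
    list has no false positive.
    """
    if pred.L != native.L:
        raise ValueError("prediction and native sizes differ")
    if k is None:
        k = top_k(0.2, pred.L)
    ranked = [
        p
        for p in rank_pairs(pred, range_class)
        if _assessable(native, p[0], p[1]) and p[2] > 0
    ]
    fp_d = [
        native.dist[i - 1, j - 1]
        for i, j, _ in ranked[:k]
        if not _is_contact(native, i, j, contact_threshold)
    ]
    if not fp_d:
        return None
    return float(np.mean(fp_d))


def restrict_to_domain(obj, segment: DomainSegment):
    """Submatrix of a ContactMap or DistanceMatrix over [start, end].

    Domain-level evaluation only filters which pairs are assessed: because
    both residues of an assessed pair lie inside the segment, sequence
    separations are unchanged by the common index shift, so range bands keep
    their full-chain meaning.
    """
    L = obj.L
    if segment.end > L:
        raise ValueError(f"segment {segment} exceeds size {L}")
    lo, hi = segment.start - 1, segment.end
    if isinstance(obj, ContactMap):
        return ContactMap(
            prob=obj.prob[lo:hi, lo:hi].copy(),
            threshold_angstrom=obj.threshold_angstrom,
        )
    if isinstance(obj, DistanceMatrix):
        return DistanceMatrix(dist=obj.dist[lo:hi, lo:hi].copy(), source=obj.source)
    raise TypeError(f"cannot restrict object of type {type(obj).__name__}")


def one_per_residue_filter(
    ranked: Sequence[tuple[int, int, float]]
) -> list[tuple[int, int, float]]:
    """Greedy de-redundancy: scan the ranked list and keep a pair only if
    neither residue has appeared in an already-kept pair. Counters the
    tendency of top-k lists to concentrate in one contact cluster."""
    used: set[int] = set()
    kept = []
    for i, j, p in ranked:
        if i in used or j in used:
            continue
        kept.append((i, j, p))
        used.add(i)
        used.add(j)
    return kept


def evaluate_map(
    pred: ContactMap,
    native: DistanceMatrix,
    ranges: Iterable[str] = ("short", "medium", "long"),
    fractions: dict[str, float] | None = None,
    contact_threshold: float = CONTACT_THRESHOLD,
    one_per_residue: bool = False,
) -> dict:
    """Full scorecard: per-band precisions at the standard top-k fractions,
    plus AUC, coverage at top L and mean false-positive distance at top L/5."""
    fractions = fractions or STANDARD_FRACTIONS
    out: dict = {}
    L = pred.L
    for rname in ranges:
        rc = RANGES[rname]
        entry: dict = {}
        for fname, frac in fractions.items():
            entry[f"precision_{fname}"] = precision_topk(
                pred,
                native,
                fraction=frac,
                range_class=rc,
                contact_threshold=contact_threshold,
                one_per_residue=one_per_residue,
            )
        entry["auc"] = roc_auc(pred, native, rc, contact_threshold)
        entry["coverage_topL"] = coverage_stat(
            pred, native, k=top_k(1.0, L), range_class=rc,
            contact_threshold=contact_threshold,
        )
        entry["mean_fp_distance_topL5"] = mean_fp_distance(
            pred, native, range_class=rc, contact_threshold=contact_threshold
        )
        out[rname] = entry
    return out
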