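"""Ab initio domain detection from alignment coverage profiles.

When a full-length sequence search is dominated by one well-represented
domain, the other domains end up with far fewer homologs in the alignment.
Such under-represented regions can be located directly from the alignment:
count the rows covering each query position, take the median of those counts
as a cutoff, and report every run of at least ``min_len`` consecutive
positions whose coverage is strictly below the cutoff as a "hard domain".
Searching a hard domain's sequence separately then yields a deeper domain
alignment and better coevolutionary features for it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msa import MSA, GAP_CHARS, DomainSegment


@dataclass
class CoverageProfile:
    """Per-column sequence coverage of the query, plus the median cutoff."""

    counts: np.ndarray  # non-negative ints, length L
    cutoff: float  # median of counts

    @property
    def L(self) -> int:
        return len(self.counts)


def coverage_profile(msa: MSA) -> CoverageProfile:
    """Count the rows with a non-gap character at each query position.

    The cutoff is the median of the counts (for even L, the mean of the two
    central order statistics, so it may be non-integer).
    """
    counts = (msa.codes() != 0).sum(axis=0).astype(np.int64)
    return CoverageProfile(counts=counts, cutoff=float(np.median(counts)))


def parse_hard_domains(
    profile: CoverageProfile,
    min_len: int = 30,
    merge_gap: int = 0,
) -> list[DomainSegment]:
    """Find maximal runs of positions with coverage strictly below the cutoff.

    Runs shorter than ``min_len`` residues are discarded. ``merge_gap > 0``
    additionally merges below-cutoff runs separated by at most that many
    above-cutoff positions before applying the length filter (off by
    default: the strict reading is maximal strictly-below runs only).
    Returns non-overlapping segments in ascending order; ties at the median
    do not count as below.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    below = profile.counts < profile.cutoff
    runs: list[list[int]] = []  # [start0, end0] 0-based inclusive
    start = None
    for p, b in enumerate(below):
        if b and start is None:
            start = p
        elif not b and start is not None:
            runs.append([start, p - 1])
            start = None
    if start is not None:
        runs.append([start, len(below) - 1])
    if merge_gap > 0:
        merged: list[list[int]] = []
        for run in runs:
            if merged and run[0] - merged[-1][1] - 1 <= merge_gap:
                merged[-1][1] = run[1]
            else:
                merged.append(run)
        runs = merged
    return [
        DomainSegment(start=s + 1, end=e + 1, kind="hard")
        for s, e in runs
        if e - s + 1 >= min_len
    ]


def plan_domain_prediction(
    segments: list[DomainSegment], L: int
) -> list[DomainSegment]:
    """Build the prediction work list: the full-length segment plus each hard
    domain.

    Downstream, the full-length alignment predicts the full-length contact
    map while each hard segment gets its own sliced alignment and map; the
    maps are then merged back. Overlapping hard segments cannot arise from
    :func:`parse_hard_domains` but are rejected here to guard hand-edited
    input.
    """
    hard = sorted((s for s in segments if s.kind == "hard"), key=lambda s: s.start)
    for seg in hard:
        if seg.end > L:
            raise ValueError(f"segment {seg} exceeds sequence length {L}")
    for a, b in zip(hard, hard[1:]):
        if b.start <= a.end:
            raise ValueError(f"overlapping hard segments {a} and {b}")
    return [DomainSegment(start=1, end=L, kind="full"), *hard]


def domain_summary(msa: MSA, min_len: int = 30, merge_gap: int = 0) -> list[dict]:
    """Convenience: coverage-profile + parse in one step, with per-segment
    mean coverage (what the CLI tabulates)."""
    prof = coverage_profile(msa)
    segs = parse_hard_domains(prof, min_len=min_len, merge_gap=merge_gap)
    plan = plan_domain_prediction(segs, L=prof.L)
    return [
        {
            "start": s.start,
            "end": s.end,
            "kind": s.kind,
            "mean_coverage": float(np.mean(prof.counts[s.start - 1 : s.end])),
        }
        for s in plan
    ]
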