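"""Contact maps, distance matrices, domain integration and the multi-threshold
distance-distribution algebra.

A contact map is an L x L symmetric matrix of probabilities that residue
pairs are "in contact" — Cbeta-Cbeta distance strictly below a threshold
(8.0 A by the CASP definition; Calpha for glycine). Predicting maps at
several thresholds (6, 7.5, 8, 8.5, 10 A) turns the binary contact question
into a coarse per-pair distance distribution: the per-threshold
probabilities form a CDF sampled at those thresholds, and successive
differences give the probability mass in each distance interval
(0,6], (6,7.5], (7.5,8], (8,8.5], (8.5,10], (10,inf).

Domain-level predictions are folded back into the full-length map by
elementwise maximum over the domain block: a probability is replaced by its
domain counterpart only where the latter is larger.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .msa import DomainSegment

DEFAULT_THRESHOLDS: tuple[float, ...] = (6.0, 7.5, 8.0, 8.5, 10.0)
CONTACT_THRESHOLD = 8.0

_RR_HEADER_TOKENS = {"PFRMAT", "TARGET", "AUTHOR", "REMARK", "METHOD", "MODEL", "END"}


@dataclass
class ContactMap:
    """Symmetric L x L matrix of contact probabilities at a distance threshold."""

    prob: np.ndarray
    threshold_angstrom: float = CONTACT_THRESHOLD

    def __post_init__(self) -> None:
        p = np.asarray(self.prob, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError(f"probability matrix must be square, got {p.shape}")
        if not np.allclose(p, p.T, atol=1e-8):
            raise ValueError("probability matrix must be symmetric")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        if np.any(np.abs(np.diag(p)) > 1e-12):
            raise ValueError("diagonal must be zero")
        self.prob = np.clip(p, 0.0, 1.0)

    @property
    def L(self) -> int:
        return self.prob.shape[0]


@dataclass
class DistanceMatrix:
    """Symmetric L x L Cbeta-Cbeta distances in Angstrom; NaN marks a missing
    (unassessable) pair."""

    dist: np.ndarray
    source: Literal["structure", "synthetic"] = "structure"

    def __post_init__(self) -> None:
        d = np.asarray(self.dist, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError(f"distance matrix must be square, got {d.shape}")
        both = ~np.isnan(d)
        if not np.allclose(np.where(both, d, 0.0), np.where(both.T, d.T, 0.0), atol=1e-6):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(np.nan_to_num(d))) > 1e-9):
            raise ValueError("diagonal must be zero")
        off = d[~np.eye(d.shape[0], dtype=bool)]
        if np.any(off[~np.isnan(off)] <= 0):
            raise ValueError("off-diagonal distances must be positive")
        self.dist = d

    @property
    def L(self) -> int:
        return self.dist.shape[0]


@dataclass
class ThresholdStack:
    """Contact maps for one target at strictly increasing distance thresholds."""

    maps: list[ContactMap]

    def __post_init__(self) -> None:
        if not self.maps:
            raise ValueError("empty stack")
        L = self.maps[0].L
        if any(m.L != L for m in self.maps):
            raise ValueError("all maps in a stack must share L")
        th = self.thresholds
        if any(b <= a for a, b in zip(th, th[1:])):
            raise ValueError("thresholds must be strictly increasing")

    @property
    def thresholds(self) -> tuple[float, ...]:
        return tuple(m.threshold_angstrom for m in self.maps)

    @property
    def L(self) -> int:
        return self.maps[0].L

    def as_array(self) -> np.ndarray:
        """(T, L, L) array of the per-threshold probabilities."""
        return np.stack([m.prob for m in self.maps])


# ---------------------------------------------------------------------------
# I/O


def read_contact_map(
    path: str | Path,
    format: Literal["rr", "matrix"] = "rr",
    L: int | None = None,
    threshold_angstrom: float = CONTACT_THRESHOLD,
) -> ContactMap:
    """Read a contact map from CASP RR text or a square whitespace matrix.

    RR lines are ``i j d1 d2 p`` (5-column) or ``i j p`` (3-column) with
    1-based i < j; CASP header/footer keywords and a bare sequence line are
    tolerated and skipped. Pairs not listed default to probability 0, the
    CASP convention of submitting only confident pairs. ``L`` is required
    for the RR format.
    """
    path = Path(path)
    if format == "matrix":
        mat = np.loadtxt(path, ndmin=2)
        return ContactMap(prob=mat, threshold_angstrom=threshold_angstrom)
    if format != "rr":
        raise ValueError(f"unknown format {format!r}")
    if L is None:
        raise ValueError("L is required to read RR format")
    prob = np.zeros((L, L))
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split()
        if fields[0].upper() in _RR_HEADER_TOKENS:
            continue
        if len(fields) == 1 and fields[0].isalpha():
            continue  # sequence line
        if len(fields) not in (3, 5):
            raise ValueError(f"{path}:{lineno}: expected 3 or 5 fields, got {len(fields)}")
        try:
            i, j = int(fields[0]), int(fields[1])
            p = float(fields[-1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: unparseable RR line {line!r}") from exc
        if not (1 <= i < j <= L):
            raise ValueError(f"{path}:{lineno}: need 1 <= i < j <= L, got i={i} j={j}")
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{path}:{lineno}: probability {p} outside [0, 1]")
        prob[i - 1, j - 1] = prob[j - 1, i - 1] = p
    return ContactMap(prob=prob, threshold_angstrom=threshold_angstrom)


def write_contact_map(
    cmap: ContactMap,
    path: str | Path,
    format: Literal["rr", "matrix"] = "rr",
) -> None:
    """Write RR (5-column, d1=0, d2=threshold, 6 decimals) or matrix text."""
    path = Path(path)
    if format == "matrix":
        np.savetxt(path, cmap.prob, fmt="%.6f")
        return
    if format != "rr":
        raise ValueError(f"unknown format {format!r}")
    lines = []
    L = cmap.L
    for i in range(L):
        for j in range(i + 1, L):
            p = cmap.prob[i, j]
            if p > 0:
                lines.append(
                    f"{i + 1} {j + 1} 0 {cmap.threshold_angstrom:g} {p:.6f}"
                )
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def read_distance_matrix(
    path: str | Path, source: Literal["structure", "synthetic"] = "structure"
) -> DistanceMatrix:
    """Read a square whitespace-separated distance matrix; 'nan' marks missing."""
    mat = np.loadtxt(Path(path), ndmin=2)
    return DistanceMatrix(dist=mat, source=source)


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    np.savetxt(Path(path), dm.dist, fmt="%.6f")


def read_cbeta_coordinates(path: str | Path) -> np.ndarray:
    """Read a 4-column table (resnum, x, y, z) of Cbeta coordinates.

    Residue numbers must be 1..L contiguous; rows may appear in any order.
    (For glycine, the caller supplies Calpha coordinates in the Cbeta slot,
    the CASP convention.)
    """
    table = np.loadtxt(Path(path), ndmin=2)
    if table.shape[1] != 4:
        raise ValueError(f"expected 4 columns (resnum x y z), got {table.shape[1]}")
    resnum = table[:, 0].astype(int)
    order = np.argsort(resnum)
    resnum = resnum[order]
    if not np.array_equal(resnum, np.arange(1, len(resnum) + 1)):
        raise ValueError("residue numbers must be contiguous 1..L")
    return table[order, 1:4]


def distance_matrix_from_coordinates(
    coords: np.ndarray, source: Literal["structure", "synthetic"] = "structure"
) -> DistanceMatrix:
    """Pairwise Euclidean distances from an (L, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    return DistanceMatrix(dist=np.sqrt((diff**2).sum(axis=2)), source=source)


# ---------------------------------------------------------------------------
# Domain integration and threshold algebra


def merge_domain_map(
    full: ContactMap, domain: ContactMap, segment: DomainSegment
) -> ContactMap:
    """Fold a domain-level prediction into the full-length map.

    For every pair with both residues inside the segment, the output is the
    elementwise maximum of the full-length and domain probabilities: an
    entry is replaced by its domain counterpart only where the latter is
    larger. Entries outside the block are unchanged. Never decreases any
    entry; merging a map with itself is a no-op.
    """
    if segment.end > full.L:
        raise ValueError(f"segment {segment} exceeds map size {full.L}")
    if domain.L != segment.length:
        raise ValueError(
            f"domain map size {domain.L} does not match segment length {segment.length}"
        )
    if domain.threshold_angstrom != full.threshold_angstrom:
        raise ValueError("full and domain maps must share a distance threshold")
    out = full.prob.copy()
    lo, hi = segment.start - 1, segment.end
    out[lo:hi, lo:hi] = np.maximum(out[lo:hi, lo:hi], domain.prob)
    return ContactMap(prob=out, threshold_angstrom=full.threshold_angstrom)


def contacts_from_distance(
    dm: DistanceMatrix, threshold: float = CONTACT_THRESHOLD
) -> ContactMap:
    """Binary native contact map: 1 where distance is strictly below the
    threshold. Missing distances yield 0 (the pair stays flagged as
    unassessable in the DistanceMatrix itself)."""
    with np.errstate(invalid="ignore"):
        binary = (dm.dist < threshold).astype(float)
    np.fill_diagonal(binary, 0.0)
    return ContactMap(prob=binary, threshold_angstrom=threshold)


def monotone_project(stack: ThresholdStack) -> ThresholdStack:
    """Make per-pair probabilities non-decreasing in the threshold.

    Independently predicted per-threshold maps need not satisfy
    P(d<6) <= P(d<7.5) <= ... <= P(d<10); the running maximum across
    increasing thresholds is the smallest pointwise correction that does.
    Idempotent; never decreases an entry.
    """
    arr = np.maximum.accumulate(stack.as_array(), axis=0)
    return ThresholdStack(
        maps=[
            ContactMap(prob=arr[t], threshold_angstrom=th)
            for t, th in enumerate(stack.thresholds)
        ]
    )


def interval_distribution(stack: ThresholdStack) -> np.ndarray:
    """Per-pair probability mass over the distance intervals delimited by the
    stack's thresholds, plus the open tail.

    For the default thresholds the intervals are (0,6], (6,7.5], (7.5,8],
    (8,8.5], (8.5,10], (10,inf). Returns an (L, L, T+1) array whose slices
    are successive differences of the per-threshold CDF plus 1 - P(d<max);
    each pair's values are non-negative and sum to 1. The stack must already
    be monotone — apply :func:`monotone_project` first.
    """
    cdf = stack.as_array()  # (T, L, L)
    if np.any(np.diff(cdf, axis=0) < -1e-12):
        raise ValueError(
            "stack is not monotone across thresholds; apply monotone_project first"
        )
    T = cdf.shape[0]
    parts = [cdf[0]]
    parts.extend(cdf[t] - cdf[t - 1] for t in range(1, T))
    parts.append(1.0 - cdf[-1])
    return np.clip(np.stack(parts, axis=-1), 0.0, None)


def interval_edges(stack: ThresholdStack) -> list[tuple[float, float]]:
    """The (low, high] distance intervals matching interval_distribution."""
    th = stack.thresholds
    edges = [(0.0, th[0])]
    edges.extend(zip(th, th[1:]))
    edges.append((th[-1], float("inf")))
    return edges
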