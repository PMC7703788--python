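"""Synthetic fixtures: alignments with engineered redundancy and coverage
dips, toy 3D chains, and noisy predicted contact maps.

These generators emulate the regimes the analysis modules are designed to
probe — alignment depth/diversity (Neff), under-covered domains, and
predictors of tunable quality — without any database search or trained
model. Every generator is a pure function of its recipe: the same seed
yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .maps import ContactMap, DistanceMatrix, distance_matrix_from_coordinates
from .msa import AMINO_ACIDS, MSA


@dataclass
class MsaRecipe:
    """Recipe for an alignment with controlled redundancy and coverage.

    ``redundancy_blocks`` is a list of (block_size, mutation_rate): each
    block is block_size copies of one base sequence, each position of each
    copy mutated independently with the given probability. Blocks draw from
    disjoint residue alphabets, so distinct blocks share no identity; with
    mutation rate 0 a recipe of B blocks therefore has Neff = B exactly.
    The query is the unmutated base sequence of the first block (row 0).

    ``coverage_dips`` is a list of (start, end, fraction): the stated
    fraction of non-query rows is gapped across the 1-based inclusive
    interval, carving a coverage trough the domain parser can detect.

    ``n_rows`` beyond the blocks' total is filled with unrelated random
    rows; None means exactly the blocks' total.
    """

    L: int
    redundancy_blocks: list[tuple[int, float]]
    n_rows: int | None = None
    coverage_dips: list[tuple[int, int, float]] = field(default_factory=list)
    alphabet: str = AMINO_ACIDS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if not self.redundancy_blocks or self.redundancy_blocks[0][0] < 1:
            raise ValueError("need at least one non-empty redundancy block")
        for size, rate in self.redundancy_blocks:
            if size < 1 or not (0.0 <= rate <= 1.0):
                raise ValueError(f"bad block ({size}, {rate})")
        for s, e, frac in self.coverage_dips:
            if not (1 <= s <= e <= self.L):
                raise ValueError(f"dip [{s}, {e}] outside [1, {self.L}]")
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"dip fraction {frac} outside [0, 1]")
        total = sum(size for size, _ in self.redundancy_blocks)
        if self.n_rows is not None and self.n_rows < total:
            raise ValueError("n_rows smaller than the blocks' total")


def gen_msa(recipe: MsaRecipe) -> MSA:
    """Generate an alignment from a redundancy/coverage recipe."""
    rng = np.random.default_rng(recipe.seed)
    B = len(recipe.redundancy_blocks)
    if B > len(recipe.alphabet):
        raise ValueError("more blocks than alphabet letters; cannot keep them disjoint")
    # split the alphabet into B disjoint slices, one per block
    per = len(recipe.alphabet) // B
    slices = [recipe.alphabet[b * per : (b + 1) * per] for b in range(B)]
    slices[-1] = recipe.alphabet[(B - 1) * per :]
    for (size, rate), sl in zip(recipe.redundancy_blocks, slices):
        if rate > 0 and len(sl) < 2:
            raise ValueError("mutation needs >= 2 letters per block alphabet")

    rows: list[str] = []
    for (size, rate), sl in zip(recipe.redundancy_blocks, slices):
        letters = np.array(list(sl))
        base = rng.integers(0, len(letters), size=recipe.L)
        for r in range(size):
            seq = base.copy()
            if rate > 0 and not (not rows and r == 0):
                mutate = rng.random(recipe.L) < rate
                # draw a different letter within the block's alphabet
                shift = rng.integers(1, len(letters), size=recipe.L)
                seq = np.where(mutate, (seq + shift) % len(letters), seq)
            rows.append("".join(letters[seq]))
    total = len(rows)
    n_rows = recipe.n_rows if recipe.n_rows is not None else total
    full = np.array(list(recipe.alphabet))
    for _ in range(n_rows - total):
        rows.append("".join(full[rng.integers(0, len(full), size=recipe.L)]))

    grid = np.array([list(r) for r in rows], dtype="U1")
    for s, e, frac in recipe.coverage_dips:
        k = min(round(frac * len(rows)), len(rows) - 1)
        victims = rng.choice(np.arange(1, len(rows)), size=k, replace=False)
        grid[victims, s - 1 : e] = "-"
    rows = ["".join(r) for r in grid]
    return MSA(
        query_id="synthetic_query",
        query_seq=rows[0],
        rows=rows,
        row_ids=[f"row{i}" for i in range(len(rows))],
    )


@dataclass
class ChainRecipe:
    """Recipe for a toy 3D chain yielding a Cbeta-like distance matrix.

    ``helix-like`` places residues on an ideal alpha-helical spiral
    (constant consecutive distance); ``random-walk`` grows a self-avoiding
    walk with fixed step length, rejecting any placement closer than
    ``clash`` A to a non-adjacent residue. The walk is confined to a sphere
    of radius ``confine_radius`` so the chain collapses into a compact
    globule the way folded proteins do — an unconfined walk is too extended
    to form the long-range contacts the evaluation metrics target. The
    default radius scales as 3.5 * L^(1/3) A, roughly constant packing
    density; None keeps the default, float('inf') disables confinement.
    """

    L: int
    mode: Literal["helix-like", "random-walk"] = "random-walk"
    step: float = 3.8
    clash: float = 3.6
    confine_radius: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError("L must be >= 2")
        if self.step <= self.clash:
            raise ValueError("step must exceed the clash distance")
        if self.confine_radius is None:
            self.confine_radius = 3.5 * self.L ** (1.0 / 3.0)
        if self.confine_radius <= self.step:
            raise ValueError("confinement radius must exceed the step length")


def gen_chain(recipe: ChainRecipe) -> tuple[np.ndarray, DistanceMatrix]:
    """Generate chain coordinates and the derived distance matrix."""
    if recipe.mode == "helix-like":
        coords = _helix_coords(recipe.L)
    elif recipe.mode == "random-walk":
        coords = _self_avoiding_walk(recipe)
    else:
        raise ValueError(f"unknown mode {recipe.mode!r}")
    return coords, distance_matrix_from_coordinates(coords, source="synthetic")


def _helix_coords(L: int) -> np.ndarray:
    # ideal alpha-helix Calpha geometry: r = 2.3 A, 100 deg and 1.5 A rise per residue
    t = np.arange(L)
    theta = np.deg2rad(100.0) * t
    return np.column_stack(
        [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * t]
    )


def _self_avoiding_walk(recipe: ChainRecipe, max_tries: int = 200) -> np.ndarray:
    rng = np.random.default_rng(recipe.seed)
    coords = np.zeros((recipe.L, 3))
    i = 1
    while i < recipe.L:
        for attempt in range(max_tries):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            candidate = coords[i - 1] + recipe.step * direction
            if np.linalg.norm(candidate) > recipe.confine_radius:
                continue
            if i < 2:
                break
            d = np.linalg.norm(coords[: i - 1] - candidate, axis=1)
            if np.all(d >= recipe.clash):
                break
        else:
            # dead end: back up one residue and retry
            i = max(1, i - 1)
            continue
        coords[i] = candidate
        i += 1
    return coords


def gen_predictions(
    truth: ContactMap,
    tp_signal: float = 0.6,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> ContactMap:
    """Noisy predictor emulation: clip(tp_signal * truth + N(0, noise_sd), 0, 1).

    Noise is drawn on the upper triangle and mirrored so the map stays
    symmetric. Larger tp_signal / noise_sd gives cleaner separation between
    true and false pairs (higher AUC); tp_signal = 0 gives pure noise with
    AUC ~ 0.5.
    """
    rng = np.random.default_rng(seed)
    L = truth.L
    noise = np.zeros((L, L))
    iu = np.triu_indices(L, k=1)
    noise[iu] = rng.normal(0.0, noise_sd, size=len(iu[0]))
    noise = noise + noise.T
    score = np.clip(tp_signal * truth.prob + noise, 0.0, 1.0)
    np.fill_diagonal(score, 0.0)
    return ContactMap(prob=score, threshold_angstrom=truth.threshold_angstrom)
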