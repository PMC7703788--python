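"""Two-stage multi-threshold network topology and receptive-field arithmetic.

The prediction architecture this models is a set of six convolutional
networks used in two stages. Five stage-1 networks each predict a contact
map at one distance threshold (6, 7.5, 8, 8.5, 10 A); together their
outputs form a coarse per-pair distance distribution. The single stage-2
network consumes that distribution alongside the original features and
emits the final 8 A contact map.

What makes stacked convolutions effective for contact maps is the receptive
field: with stride 1, n layers of k x k kernels let each output cell see a
(1 + n*(k-1))-wide square of the input, so the network can exploit
correlations between contacts (e.g. the diagonal stripes two paired beta
strands produce) rather than scoring each residue pair in isolation. A
7-layer stack of 5 x 5 filters sees 29 x 29; the two-stage composition,
counted as 13 effective layers, sees 53 x 53.

Training is deliberately out of scope: predictors are injected callables,
so the two-stage data flow is exercised with mocks or any trained model
honouring the map-in/map-out contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .maps import DEFAULT_THRESHOLDS, ContactMap, ThresholdStack


@dataclass(frozen=True)
class ConvStackSpec:
    """A stack of stride-1 convolutional layers with square odd kernels."""

    n_layers: int
    kernel: int = 5
    stride: int = 1

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValueError("kernel must be odd >= 1 (even kernels have no center)")
        if self.stride != 1:
            raise ValueError("only stride 1 is supported")


#: one network: 6 hidden conv layers + 1 output layer, all 5x5
DEFAULT_SINGLE_STACK = ConvStackSpec(n_layers=7, kernel=5)


@dataclass(frozen=True)
class TwoStageSpec:
    """Topology of the six-network, two-stage predictor.

    ``effective_total_layers`` is the layer count used for the whole
    network's receptive field. The printed arithmetic for the two chained
    7-layer stacks counts 12 kernel increments, i.e. 13 effective layers
    (not 14): the stage-2 input already is a map, so one layer's growth is
    not double-counted. Both conventions are available — use
    :func:`compose_stages` for the plain sum.
    """

    stage1_thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    stage2_threshold: float = 8.0
    stack: ConvStackSpec = DEFAULT_SINGLE_STACK
    effective_total_layers: int = 13

    @property
    def n_models(self) -> int:
        return len(self.stage1_thresholds) + 1

    def total_receptive_field(self) -> int:
        return receptive_field(
            ConvStackSpec(self.effective_total_layers, self.stack.kernel)
        )


DEFAULT_TWO_STAGE = TwoStageSpec()


def receptive_field(stack: ConvStackSpec) -> int:
    """Side length of the input square one output cell can see.

    Each stride-1 layer of kernel k grows the field by k-1, starting from 1:
    1 + n_layers*(k-1). For k=5: 7 layers -> 29, 13 layers -> 53.
    """
    return 1 + stack.n_layers * (stack.kernel - 1)


def compose_stages(stage1: ConvStackSpec, stage2: ConvStackSpec) -> ConvStackSpec:
    """Chain two stacks: layer counts add; kernels must match."""
    if stage1.kernel != stage2.kernel:
        raise ValueError("cannot compose stacks with different kernels")
    return ConvStackSpec(
        n_layers=stage1.n_layers + stage2.n_layers, kernel=stage1.kernel
    )


Predictor = Callable[..., np.ndarray]


def _validate_predictor_output(arr: np.ndarray, L: int, who: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.shape != (L, L):
        raise ValueError(f"{who}: output shape {arr.shape}, expected {(L, L)}")
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError(f"{who}: output probabilities outside [0, 1]")
    # orchestrator symmetrizes and zeroes the diagonal
    sym = 0.5 * (arr + arr.T)
    np.fill_diagonal(sym, 0.0)
    return sym


def run_two_stage(
    features: np.ndarray,
    stage1_predictors: Sequence[Predictor],
    stage2_predictor: Predictor,
    spec: TwoStageSpec = DEFAULT_TWO_STAGE,
) -> tuple[ThresholdStack, ContactMap]:
    """Orchestrate the two-stage flow with pluggable predictors.

    Each stage-1 predictor is called with ``features`` and must return an
    (L, L) probability map for its threshold; their maps form the
    ThresholdStack (the predicted distance distribution). The stage-2
    predictor is called with ``(stack, features)`` and returns the final
    map at ``spec.stage2_threshold``. Outputs are symmetrized (mean of M
    and M^T) and diagonal-zeroed by the orchestrator; anything outside
    [0, 1] or of the wrong shape is a contract violation.
    """
    features = np.asarray(features)
    L = features.shape[-1]
    if len(stage1_predictors) != len(spec.stage1_thresholds):
        raise ValueError(
            f"need {len(spec.stage1_thresholds)} stage-1 predictors, "
            f"got {len(stage1_predictors)}"
        )
    maps = []
    for th, predict in zip(spec.stage1_thresholds, stage1_predictors):
        out = _validate_predictor_output(
            predict(features), L, f"stage-1 predictor at {th} A"
        )
        maps.append(ContactMap(prob=out, threshold_angstrom=th))
    stack = ThresholdStack(maps=maps)
    final = _validate_predictor_output(
        stage2_predictor(stack, features), L, "stage-2 predictor"
    )
    return stack, ContactMap(prob=final, threshold_angstrom=spec.stage2_threshold)
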