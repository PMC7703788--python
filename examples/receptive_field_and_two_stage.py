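"""Receptive-field arithmetic and the two-stage prediction data flow.

A stride-1 stack of n layers with k x k kernels lets one output cell see a
(1 + n*(k-1))-wide square of the input contact map — the window within
which the network can exploit correlations between contacts. The two-stage
flow is exercised with mock predictors: five stage-1 callables produce the
per-threshold stack, a stage-2 callable turns stack + features into the
final 8 A map.
"""

import numpy as np

from contactlens import (
    DEFAULT_TWO_STAGE,
    ConvStackSpec,
    receptive_field,
    run_two_stage,
)

single = ConvStackSpec(n_layers=7, kernel=5)
print(f"7-layer 5x5 stack:  receptive field {receptive_field(single)} x "
      f"{receptive_field(single)}")
print(f"two-stage network ({DEFAULT_TWO_STAGE.effective_total_layers} effective "
      f"layers): {DEFAULT_TWO_STAGE.total_receptive_field()} x "
      f"{DEFAULT_TWO_STAGE.total_receptive_field()}")

# mock predictors: each stage-1 model "predicts" a stored map; stage 2
# averages the stack — any trained model honouring the contract plugs in.
L = 10
rng = np.random.default_rng(0)
stored = []
for _ in range(5):
    m = np.triu(rng.random((L, L)), k=1)
    stored.append(m + m.T)
stage1 = [lambda feats, m=m: m for m in stored]
stage2 = lambda stack, feats: stack.as_array().mean(axis=0)

stack, final = run_two_stage(np.zeros((1, L, L)), stage1, stage2)
print(f"\nstage-1 stack: {len(stack.maps)} maps at {stack.thresholds} A")
print(f"final 8 A map: L = {final.L}, mean prob {final.prob.mean():.3f} "
      f"(= mean of the stack by construction)")
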