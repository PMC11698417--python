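"""Structured pruning scored by channel attention.

Builds a small model, scores kernel importance on a few batches, removes
the bottom 20% per convolution, and verifies the surgery with the
masking-equivalence oracle (zeroing pruned kernels in the original net
reproduces the pruned net's outputs).
"""

import copy

import numpy as np

from octlayers.network import ModelSpec, build_model, count_parameters
from octlayers.pruning import (accumulate_importance, apply_prune,
                               mask_pruned_channels, plan_prune)

net = build_model(ModelSpec(n_classes=4, channels=(8, 16, 16, 16, 16)),
                  seed=0)
batches = [np.random.default_rng(i).random((4, 64, 64), dtype=np.float32)
           for i in range(3)]

table = accumulate_importance(net, batches)
plan = plan_prune(table, r_p=0.2, min_kept=4)
pruned = apply_prune(net, plan)

print(f"parameters: {count_parameters(net)} -> {count_parameters(pruned)} "
      f"({100 * count_parameters(pruned) / count_parameters(net):.1f}% kept)")

masked = copy.deepcopy(net)
mask_pruned_channels(masked, plan)
pruned.eval(), masked.eval()
sp, _ = pruned(batches[0])
sm, _ = masked(batches[0])
print(f"masking-equivalence max deviation: {np.abs(sp.data - sm.data).max():.2e}")
# ~1e-7: removing a kernel and zeroing it are the same computation
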