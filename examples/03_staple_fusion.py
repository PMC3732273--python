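"""Fuse noisy rater segmentations with consensus-restricted STAPLE + MRF.

Nine raters with known sensitivity 0.90 and specificity 0.95 are simulated
from a synthetic truth; STAPLE recovers both rates and a fused label better
than any single rater.
"""

import numpy as np

from atlasmanifold import dice, generate_library, majority_vote, simulate_raters, staple

truth = generate_library(n=4, q=3, grid_dims=(24, 24, 24), amplitude=2.5, seed=1).reference
stack = simulate_raters(truth, p=0.90, q_spec=0.95, R=9, seed=7)

result = staple(stack, beta=0.2)
print(f"EM converged in {result.iterations} iterations")
print(f"estimated sensitivity: {np.round(result.sensitivity, 3)} (true 0.90)")
print(f"estimated specificity: {np.round(result.specificity, 3)} (true 0.95)")

from atlasmanifold import LabelMap  # single-rater comparison

single = LabelMap(grid=truth.grid, values=stack.decisions[0])
print(f"Dice vs truth: STAPLE {dice(result.fused, truth):.4f}, "
      f"majority vote {dice(majority_vote(stack), truth):.4f}, "
      f"single rater {dice(single, truth):.4f}")
print("-> fusion removes independent rater error; the MRF (beta=0.2) adds")
print("   spatial consistency in the non-consensus region only")
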