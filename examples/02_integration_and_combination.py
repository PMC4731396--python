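"""Test dorsal-lateral integration and combine the two views.

Two-block partial least squares asks whether the dorsal and lateral
shapes covary (morphological integration); if they do, analyzing the
views separately would discard shared signal, so they are merged by the
separate-subsets combination, which weights each view by its share of
centroid size and yields a combined configuration of unit centroid
size.
"""

import numpy as np

from vipermorph import (
    SimulationConfig,
    combine_subsets,
    fixed_angle_align,
    generate_study,
    gpa,
    two_block_pls,
)

study = generate_study(SimulationConfig(n_per_group=20, seed=2))
res_d = gpa(study.dorsal[0])
res_l = gpa([fixed_angle_align(c, study.articulation) for c in study.lateral[0]])

pls = two_block_pls(res_d.residual_matrix, res_l.residual_matrix, n_perm=999, seed=2)
print(f"r_PLS = {pls.r_pls:.4f}, permutation P = {pls.p_value:.4f} ({pls.n_permutations} permutations)")

combined = combine_subsets(
    res_d.aligned[0].ravel(),
    res_l.aligned[0].ravel(),
    res_d.centroid_sizes[0],
    res_l.centroid_sizes[0],
)
coords = combined.y_total.reshape(-1, 2)
cs = np.linalg.norm(coords - coords.mean(axis=0))
print(f"dorsal weight (share of squared centroid size): {combined.dorsal_weight:.3f}")
print(f"combined centroid size: {cs:.12f}")

# A small P means the first PLS axes of the two views are significantly
# correlated: the views are integrated and the combined vector (unit
# centroid size by construction) is the right unit of analysis.
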