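"""Detect a node-localized brain-behavior effect with cluster permutation FWE.

Embeds a Spearman rho = -0.45 association between MD at nodes 17-22 and
speaking rate into an otherwise null 45-subject cohort, then runs the
along-tract cluster-size permutation test. The printed cluster should
overlap nodes 17-22; the critical cluster size is the run length that
fewer than 5% of permuted cohorts reach by chance.
"""

import numpy as np

from tractofluency import (
    StatsConfig,
    cluster_permutation_fwe,
    embed_effect,
    generate_scalar_profiles,
    partial_spearman,
)

rng = np.random.default_rng(7)
n = 45
md = generate_scalar_profiles(n, np.full(30, 7.3e-4), 2.5e-5, 3e-5, seed=5)
speaking = rng.normal(5.04, 0.68, size=n)
articulation = speaking + np.abs(rng.normal(1.4, 0.8, size=n))
md = embed_effect(md, speaking, (17, 22), -0.45)

result = cluster_permutation_fwe(
    md, speaking, StatsConfig(n_permutations=1000, seed=6),
    tract="MCP_R", metric="MD", behavior_name="speaking_rate",
)
print(f"critical cluster size: {result.critical_cluster_size} nodes")
for start, end, mean_rho in result.clusters:
    print(f"significant cluster: nodes {start}-{end}, mean rho = {mean_rho:+.3f}")
    cluster_md = md[:, start - 1 : end].mean(axis=1)
    follow = partial_spearman(cluster_md, speaking, articulation)
    print(f"  partial rho controlling articulation rate: {follow['rho']:+.3f} "
          f"(p = {follow['p']:.4f})")
if not result.clusters:
    print("no cluster survived the familywise correction in this draw")
print("A surviving cluster means the run of suprathreshold nodes is longer "
      "than chance produces across the 30-node tract.")
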