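"""Generate a synthetic cohort and inspect its behavioral correlation structure.

Builds 45 subjects with the four speech-fluency measures drawn from a
Gaussian copula, then prints the empirical Spearman intercorrelation
matrix: the two rate measures should correlate around 0.6, the two
verbal-fluency scores around 0.55, and the cross-block entries should sit
near zero.
"""

import numpy as np
from scipy.stats import spearmanr

from tractofluency import generate_behavior

table = generate_behavior(n_subjects=45, seed=1)
print(table.head().round(2), "\n")

corr = spearmanr(table.to_numpy()).statistic
labels = list(table.columns)
print("Empirical Spearman intercorrelations (n=45):")
for i, row in enumerate(corr):
    print(f"  {labels[i]:<18}" + "  ".join(f"{v:+.2f}" for v in row))

print(
    "\nArticulation rate exceeds speaking rate for every subject:",
    bool((table.articulation_rate >= table.speaking_rate).all()),
)
print(
    "At n=45 the empirical correlations scatter around their targets "
    "(0.599 rates, 0.548 fluency); rerun with n_subjects=2000 to see them converge."
)
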