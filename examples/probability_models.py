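"""The closed-form probability machinery behind detection and correction."""

import numpy as np

from pedanc import (
    diploid_transition,
    double_crossover_prob,
    expected_dosage_error,
    haploid_transition,
    inference_matrix,
)

# Ancestry-switch transition over 0.02 Morgans (2 cM), tau=8 generations,
# 80% population-A ancestry: rows = source state, columns = destination.
print("haploid transition (2 cM):")
print(np.round(haploid_transition(0.02, tau=8, lamb=0.8), 6))
print("diploid dosage transition (2 cM):")
print(np.round(diploid_transition(0.02, tau=8, lamb=0.8), 6))

# Observation model: P(called dosage | true dosage) with 1% allele flips.
print("inference matrix (epsilon=0.01):")
print(np.round(inference_matrix(0.01), 6))

# Expected dosage error rate E|Y-X| implied by epsilon and lambda.
print("expected dosage error:", round(expected_dosage_error(0.01, 0.8), 6))

# Probability of >= 2 true crossovers within 2 cM at tau=8: short
# double crossovers in calls are far more likely errors than biology.
print("P(>=2 crossovers in 2 cM):", round(double_crossover_prob(0.02, 8), 6))
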