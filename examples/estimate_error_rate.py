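"""Estimate the allelic ancestry-call error rate from Mendelian errors.

Upstream local-ancestry software run on family members as if they were
unrelated leaves Mendelian inconsistencies in the calls. Their count in
nuclear families pins down the per-allele error rate epsilon without any
truth data: the expected per-locus Mendelian-error rate is a known
quadratic in epsilon.
"""

import numpy as np

from pedanc import SimConfig, demo_map, demo_pedigree, simulate_pedigree
from pedanc.detect_correct import estimate_epsilon_from_matrix

ped = demo_pedigree(20)
gmap = demo_map(L=2000)

for eps_true in (0.01, 0.03):
    sim = simulate_pedigree(ped, gmap, SimConfig(epsilon=eps_true), seed=1)
    est = estimate_epsilon_from_matrix(sim.observed, ped, lamb=0.8)
    print(
        f"injected epsilon={eps_true:.3f}  estimated={est.epsilon:.4f}  "
        f"from {len(est.families)} nuclear families, "
        f"{sum(est.me_counts)} Mendelian-error loci"
    )
# The estimate tracks the injected rate from a single 20-person pedigree.
# It runs slightly low, and more so at higher error rates: the estimator
# assumes at most one erring member per family-locus, which large sibships
# violate more often. Pooling many families tightens the estimate (the
# dedicated recovery experiment with 50 families stays within ~12%).
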