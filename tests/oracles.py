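"""Independent brute-force oracles used by several test modules.

These deliberately avoid the library's genotype-elimination and
candidate-restriction code paths: consistency is decided by exhaustive
search over ordered allele-pair assignments, and the MAP scorer loops over
the full consistent set with plain ``math.log`` accumulation.
"""

import itertools
import math

import numpy as np

from pedanc import diploid_transition, inference_matrix

PAIRS_FOR_DOSAGE = {0: [(0, 0)], 1: [(0, 1), (1, 0)], 2: [(1, 1)], -1: [(0, 0), (0, 1), (1, 0), (1, 1)]}


def oracle_consistent(config, ped) -> bool:
    """Exhaustive search for an ordered allele assignment (allele 1
    paternal, allele 2 maternal) realizing the dosage configuration."""
    config = list(config)
    choices = [PAIRS_FOR_DOSAGE[int(d)] for d in config]
    ids = ped.ids
    for assignment in itertools.product(*choices):
        ok = True
        for ind in ped.individuals:
            a1, a2 = assignment[ped.index_of(ind.id)]
            if ind.father_id is not None:
                if a1 not in assignment[ped.index_of(ind.father_id)]:
                    ok = False
                    break
            if ind.mother_id is not None:
                if a2 not in assignment[ped.index_of(ind.mother_id)]:
                    ok = False
                    break
        if ok:
            return True
    return False


def oracle_ped_set(ped):
    """All Mendelian-consistent configurations by brute force."""
    return [
        cfg
        for cfg in itertools.product((0, 1, 2), repeat=ped.n)
        if oracle_consistent(cfg, ped)
    ]


def oracle_map(y, x_left, x_right, d_left, d_right, ped, params):
    """Brute-force MAP configuration over the full consistent set, with the
    same tie-break rule (closest to y, then lexicographic)."""
    y = np.asarray(y)
    logP = np.log(np.maximum(inference_matrix(params.epsilon), 1e-300))
    Tl = (
        None
        if x_left is None
        else np.log(np.maximum(diploid_transition(d_left, params.tau, params.lamb), 1e-300))
    )
    Tr = (
        None
        if x_right is None
        else np.log(np.maximum(diploid_transition(d_right, params.tau, params.lamb), 1e-300))
    )
    scored = []
    for cfg in oracle_ped_set(ped):
        s = 0.0
        for i, x in enumerate(cfg):
            s += logP[x, y[i]]
            if Tl is not None:
                s += Tl[x_left[i], x]
            if Tr is not None:
                s += Tr[x, x_right[i]]
        scored.append((s, cfg))
    best = max(s for s, _ in scored)
    ties = [cfg for s, cfg in scored if s >= best - 1e-12]
    ties.sort(key=lambda cfg: (sum(a != b for a, b in zip(cfg, y)), cfg))
    return ties[0], best
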