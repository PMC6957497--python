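"""Representative demo pedigrees and maps for examples and simulations.

Three synthetic family structures — large (n=20), medium (n=10) and small
(n=4) — representative of the three-generation African-American study
pedigrees this method targets. They are constructed here, not copies of
any real family.
"""

from __future__ import annotations

from .ancestry_io import GeneticMap
from .pedigree import Pedigree, parse_pedigree
from .simulate import uniform_map

# fam-dialect: family, individual, father, mother, sex, phenotype
DEMO_FAM_4 = """\
F4 p1 0 0 1 -9
F4 p2 0 0 2 -9
F4 c1 p1 p2 1 -9
F4 c2 p1 p2 2 -9
"""

DEMO_FAM_10 = """\
F10 gf 0 0 1 -9
F10 gm 0 0 2 -9
F10 p1 gf gm 1 -9
F10 p2 gf gm 2 -9
F10 p3 gf gm 1 -9
F10 s1 0 0 2 -9
F10 k1 p1 s1 1 -9
F10 k2 p1 s1 2 -9
F10 k3 p1 s1 1 -9
F10 k4 p1 s1 2 -9
"""

DEMO_FAM_20 = """\
F20 gf 0 0 1 -9
F20 gm 0 0 2 -9
F20 p1 gf gm 1 -9
F20 p2 gf gm 2 -9
F20 p3 gf gm 1 -9
F20 p4 gf gm 2 -9
F20 s1 0 0 2 -9
F20 s2 0 0 1 -9
F20 s3 0 0 2 -9
F20 k1 p1 s1 1 -9
F20 k2 p1 s1 2 -9
F20 k3 p1 s1 1 -9
F20 k4 p1 s1 2 -9
F20 k5 s2 p2 1 -9
F20 k6 s2 p2 2 -9
F20 k7 s2 p2 1 -9
F20 k8 s2 p2 2 -9
F20 k9 p3 s3 1 -9
F20 k10 p3 s3 2 -9
F20 k11 p3 s3 1 -9
"""

_FAM_TEXT = {4: DEMO_FAM_4, 10: DEMO_FAM_10, 20: DEMO_FAM_20}


def demo_pedigree(n: int) -> Pedigree:
    """A representative pedigree of size n in {4, 10, 20}."""
    if n not in _FAM_TEXT:
        raise ValueError(f"demo pedigrees exist for n in {{4, 10, 20}}, got {n}")
    (ped,) = parse_pedigree(_FAM_TEXT[n])
    return ped


def demo_map(L: int = 2000, spacing_cm: float = 0.03) -> GeneticMap:
    """A uniform chromosome-22-like map (default 2000 markers over 60 cM)."""
    return uniform_map(L, spacing_cm=spacing_cm, chrom="22")
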