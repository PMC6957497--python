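import pytest

from pedanc import parse_pedigree

TRIO_FAM = """\
T1 f 0 0 1 -9
T1 m 0 0 2 -9
T1 c f m 1 -9
"""


@pytest.fixture
def trio():
    (ped,) = parse_pedigree(TRIO_FAM)
    return ped


# 3-generation, 8-person pedigree: grandparents gf/gm, their children p1/p2,
# married-in spouse s1, grandchildren k1/k2/k3 (children of p1 x s1)
EIGHT_FAM = """\
E1 gf 0 0 1 -9
E1 gm 0 0 2 -9
E1 p1 gf gm 1 -9
E1 p2 gf gm 2 -9
E1 s1 0 0 2 -9
E1 k1 p1 s1 1 -9
E1 k2 p1 s1 2 -9
E1 k3 p1 s1 1 -9
"""


@pytest.fixture
def eight_person():
    (ped,) = parse_pedigree(EIGHT_FAM)
    return ped
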