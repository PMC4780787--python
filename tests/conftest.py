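import numpy as np
import pytest

from quartetnet import parse_enewick

# single-descendant hybrid (3-cycle): shared internal exposure 1, extra 2,
# minor inheritance 0.3 — the worked case with CFs (0.81837, 0.09082, 0.09082)
SINGLE_DESC = ("((a:1,b:1):0.5,((#H1:0.1::0.3,d:1):2,"
               "(c:1)#H1:0.1::0.7):0.5);")

# two-descendant hybrid (2-cycle): cherry (a,b) below the hybrid, all
# relevant lengths 1, minor inheritance 0.2 — major CF 0.94856
TWO_DESC = "((((a:1,b:1):1)#H1:1::0.8,#H1:1::0.2):0.5,(c:1,d:1):0.5);"

# 5-taxon good diamond (hybrid parent with a 2-taxon subtree)
GOOD_DIAMOND5 = ("((((e:0.1)#H1:0.3::0.7,(a:0.5,b:0.5):0.4):0.6,"
                 "(#H1:0.2::0.3,d:0.7):0.8):0.9,f:0.5);")

# 6-taxon bad diamond II (2-taxon subtree below the hybrid node)
BAD_DIAMOND2_6 = ("(((((a:0.4,b:0.4):0.3)#H1:0.25::0.7,p:0.5):0.6,"
                  "(#H1:0.45::0.3,q:0.5):0.5):0.8,r:0.5);")

# 7 taxa, two reticulations: a 3-cycle (k=3) and a 4-cycle (k=4)
TWO_CYCLES7 = ("(((a1:0.3,a2:0.3):0.4,((b1:0.3,b2:0.3):0.2)"
               "#H1:0.1::0.8):0.3,(#H1:0.2::0.2,((c1:0.2)#H2:0.1::0.6,"
               "(#H2:0.1::0.4,c2:0.4):0.3):0.2):0.4,z:0.9);")


@pytest.fixture
def single_desc_net():
    return parse_enewick(SINGLE_DESC)


@pytest.fixture
def two_desc_net():
    return parse_enewick(TWO_DESC)


@pytest.fixture
def good_diamond5():
    return parse_enewick(GOOD_DIAMOND5)


@pytest.fixture
def bad_diamond2_6():
    return parse_enewick(BAD_DIAMOND2_6)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_valid_network(rng, n=None, h=None, **kw):
    """A random level-1 network for property tests (all cycle classes)."""
    from quartetnet import random_network

    n = int(rng.integers(4, 9)) if n is None else n
    h = int(rng.integers(0, 3)) if h is None else h
    kw.setdefault("searchable_only", False)
    kw.setdefault("hybrid_length", float(rng.uniform(0.0, 0.5)))
    if h == 0:
        from quartetnet import random_coalescent_tree

        return random_coalescent_tree(n, rng)
    return random_network(n, h, rng, gammas=(0.3, 0.2), **kw)
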