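import numpy as np
import pytest

from dmetpipe.synthetic_data import worked_example_fixture


@pytest.fixture(scope="session")
def worked_example():
    """8 probes x 12 samples (6 RESP / 6 NoRESP) with hand-verifiable values."""
    return worked_example_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def fisher_enumeration_oracle(a: int, b: int, c: int, d: int) -> float:
    """Independent two-sided Fisher p: full hypergeometric enumeration.

    Sums the point probabilities of every table sharing the observed margins
    whose probability is <= that of the observed table (relative tie
    tolerance 1e-7).  Kept free of any package code path it checks.
    """
    from scipy.stats import hypergeom

    n_row1, n_row2 = a + b, c + d
    n_col1 = a + c
    total = a + b + c + d
    kmin = max(0, n_col1 - n_row2)
    kmax = min(n_col1, n_row1)
    ks = np.arange(kmin, kmax + 1)
    pmf = hypergeom.pmf(ks, total, n_row1, n_col1)
    p_obs = hypergeom.pmf(a, total, n_row1, n_col1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def brute_force_frequent_itemsets(transactions, min_support):
    """Apriori-free oracle: enumerate every subset of the item universe."""
    from itertools import combinations

    tx = [frozenset(t) for t in transactions]
    n = len(tx)
    universe = sorted(set().union(*tx)) if tx else []
    out = {}
    for r in range(1, len(universe) + 1):
        for combo in combinations(universe, r):
            items = frozenset(combo)
            count = sum(items <= t for t in tx)
            if n and count / n >= min_support - 1e-12:
                out[items] = count / n
    return out
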