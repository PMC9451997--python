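import random

import pytest

from sahmine.itemset_core import Item, TransactionDB
from sahmine.feature_table import table1_fixture


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture(scope="session")
def table1_db(table1):
    return table1.to_transactions()


def random_db(rng: random.Random, max_items: int = 12, max_txns: int = 64):
    """A random small transaction database for oracle comparisons."""
    n_items = rng.randint(3, max_items)
    alphabet = [Item(chr(ord("A") + i), "1") for i in range(n_items)]
    n = rng.randint(4, max_txns)
    txns = []
    for _ in range(n):
        size = rng.randint(1, n_items)
        txns.append(frozenset(rng.sample(alphabet, size)))
    return TransactionDB(tuple(txns))


@pytest.fixture
def rng():
    return random.Random(20240917)
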