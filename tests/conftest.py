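import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from haplogeo.io_model import load_fixture
from haplogeo.haplotyping import pairwise_step_distances


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1")


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2")


@pytest.fixture(scope="session")
def step_distances(table2):
    return pairwise_step_distances(table2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def reconstitute_individuals(table1, table2):
    """Expand the population table to one coded row per individual."""
    from haplogeo.io_model import CodedMatrix

    rows = []
    ids = []
    for rec in table1.records:
        i = 0
        for hap in table1.haplotype_ids:
            for _ in range(rec.counts.get(hap, 0)):
                i += 1
                ids.append(f"{rec.code}_{i:03d}")
                rows.append(table2.row(hap))
    return CodedMatrix(ids, table2.columns, np.array(rows, dtype=object),
                       total_sites=table2.total_sites)


@pytest.fixture(scope="session")
def individuals_matrix(table1, table2):
    return reconstitute_individuals(table1, table2)
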