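import pytest

from herbnet.io_tables import (load_ct_edges, load_table1, load_table2,
                               load_table1_records)
from herbnet.network import build_network


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def table2():
    return load_table2()


@pytest.fixture(scope="session")
def table1_records():
    return load_table1_records()


@pytest.fixture(scope="session")
def ct_edges():
    return load_ct_edges()


@pytest.fixture(scope="session")
def ct_network(ct_edges, table1, table2):
    return build_network(ct_edges, "compound", "target",
                         left_nodes=table1["ingredient_id"].tolist(),
                         right_nodes=table2["uniprot_ac"].tolist())
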