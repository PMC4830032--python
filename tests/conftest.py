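import io

import pytest

from metapath_dti.hetnet import read_edge_list
from metapath_dti.metapaths import default_catalog
from metapath_dti.schema import default_schema


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def catalog(schema):
    return default_catalog(schema)


def net_from_rows(schema, rows, preregister=None):
    """Build a HetNet from (edge_id, src, tgt) tuples."""
    tsv = "".join(f"{e}\t{s}\t{t}\n" for e, s, t in rows)
    return read_edge_list(io.StringIO(tsv), schema, preregister=preregister)


@pytest.fixture()
def toy_net(schema):
    """Small fixed network: c1 similar c2; c2 binds p1, p2; c3 binds p1."""
    return net_from_rows(
        schema,
        [
            ("A11", "c1", "c2"),
            ("A2", "c2", "p1"),
            ("A2", "c2", "p2"),
            ("A2", "c3", "p1"),
        ],
    )
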