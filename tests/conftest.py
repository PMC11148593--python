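import pytest

from pilaf.simulate import FixtureSpec, simulate_bundle


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default synthetic bundle (seed 7) shared across tests."""
    out = tmp_path_factory.mktemp("bundle")
    manifest = simulate_bundle(FixtureSpec(rng_seed=7), out)
    return out, manifest


@pytest.fixture()
def triangle_pair():
    """Two unit-weight triangles sharing one vertex (c is the hub)."""
    import networkx as nx

    G = nx.Graph()
    for e in [("a", "b"), ("a", "c"), ("b", "c"), ("c", "d"), ("c", "e"), ("d", "e")]:
        G.add_edge(*e, weight=1.0)
    return G
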