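import pytest

from shapcoex.fixtures import make_clique_flower, make_star_of_stars


@pytest.fixture(scope="session")
def fig1():
    """Star-of-stars: hub 1, branches 2-6, three leaves each (21 nodes, 20 edges)."""
    return make_star_of_stars(5, 3)


@pytest.fixture(scope="session")
def fig2():
    """Clique flower: hub 1, connectors 2-4, three 4-cliques (13 nodes, 21 edges)."""
    return make_clique_flower(3, 4)
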