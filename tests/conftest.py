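import pytest

from hubnet import InteractionNetwork


@pytest.fixture
def triangle() -> InteractionNetwork:
    return InteractionNetwork.from_edges(
        [("A", "B", 0.95), ("B", "C", 0.91), ("A", "C", 0.92)]
    )


@pytest.fixture
def star5() -> InteractionNetwork:
    """Star with center C and four leaves."""
    return InteractionNetwork.from_edges(
        [("C", leaf, 0.9) for leaf in ("L1", "L2", "L3", "L4")]
    )


@pytest.fixture
def path3() -> InteractionNetwork:
    return InteractionNetwork.from_edges([("A", "B", 0.9), ("B", "C", 0.9)])


@pytest.fixture
def two_cliques() -> InteractionNetwork:
    """Two disjoint 5-cliques, nodes a0..a4 and b0..b4."""
    edges = []
    for prefix in ("a", "b"):
        members = [f"{prefix}{i}" for i in range(5)]
        edges += [
            (u, v, 1.0) for i, u in enumerate(members) for v in members[i + 1 :]
        ]
    return InteractionNetwork.from_edges(edges)
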