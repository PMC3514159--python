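import pytest

from y2hnet.io import GeneSet, GeneSetCollection, PPINetwork, Universe


@pytest.fixture(scope="session")
def toy_network() -> PPINetwork:
    """6-node ring with one chord: a-b-c-d-e-f-a plus a-c."""
    return PPINetwork(
        "abcdef",
        [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "f"),
         ("f", "a"), ("a", "c")],
    )


@pytest.fixture(scope="session")
def toy_collection() -> GeneSetCollection:
    return GeneSetCollection(
        "toy",
        {
            "P1": GeneSet("pathway one", frozenset("bd")),
            "P2": GeneSet("pathway two", frozenset("ef")),
        },
    )


@pytest.fixture(scope="session")
def small_universe() -> Universe:
    return Universe(frozenset(f"g{i}" for i in range(1, 11)))


@pytest.fixture(scope="session")
def hoxa1_merged():
    from y2hnet import datasets

    return datasets.hoxa1_catalog()
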