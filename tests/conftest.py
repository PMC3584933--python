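import pytest

from funclevels.go_dag import GoDag


def chain_dag(n: int = 3) -> GoDag:
    """root <- A <- B <- ... linear chain, ids GO:0000001..n."""
    ids = [f"GO:{i + 1:07d}" for i in range(n)]
    parents = {ids[0]: frozenset()}
    for i in range(1, n):
        parents[ids[i]] = frozenset({ids[i - 1]})
    return GoDag(parents, {t: "biological_process" for t in ids})


def diamond_dag() -> GoDag:
    """root <- A, root <- B, A <- C, B <- C."""
    root, a, b, c = "GO:0000001", "GO:0000002", "GO:0000003", "GO:0000004"
    parents = {
        root: frozenset(),
        a: frozenset({root}),
        b: frozenset({root}),
        c: frozenset({a, b}),
    }
    return GoDag(parents, {t: "biological_process" for t in parents})


@pytest.fixture
def chain3():
    return chain_dag(3)


@pytest.fixture
def diamond():
    return diamond_dag()


@pytest.fixture(scope="session")
def default_world():
    """One default synthetic world shared by read-only tests."""
    from funclevels.fixtures import make_world

    return make_world(seed=7)
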