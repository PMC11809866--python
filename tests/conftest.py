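import pytest

from saferec import (Account, Label, SocialGraph, default_scenario,
                     generate_corpus, generate_graph)


def make_graph(edges, labels=None, texts=None):
    """Build a small SocialGraph from an edge list and optional labels."""
    labels = labels or {}
    texts = texts or {}
    ids = sorted({u for e in edges for u in e} | set(labels) | set(texts))
    accounts = [Account(id=i, label=labels.get(i, Label.UNKNOWN),
                        texts=texts.get(i, [])) for i in ids]
    return SocialGraph(accounts, edges)


@pytest.fixture
def chain_graph():
    """u -> {a, b}; a -> c; c -> {d, e}: a minimal 3-hop expansion case."""
    return make_graph([("u", "a"), ("u", "b"), ("a", "c"),
                       ("c", "d"), ("c", "e")])


@pytest.fixture(scope="session")
def default_graph():
    """One generated instance of the shipped study scenario."""
    scenario = default_scenario()
    scenario.seed = 7
    return generate_corpus(scenario, generate_graph(scenario))
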