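import logging

import pytest

from graphfm import build_index, fixtures

# out-of-alphabet query warnings are expected noise in randomized tests
logging.getLogger("graphfm").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def named_graphs():
    return fixtures()


@pytest.fixture(scope="session")
def cyc_graph(named_graphs):
    return named_graphs["FIX-CYC"]


@pytest.fixture(scope="session")
def cyc_index(cyc_graph):
    return build_index(cyc_graph)


@pytest.fixture(scope="session")
def lin_index(named_graphs):
    return build_index(named_graphs["FIX-LIN"])


def naive_suffix_array(text: str, order: tuple[str, ...]) -> list[int]:
    """Independent oracle: sort suffixes by the explicit character order."""
    code = {c: i for i, c in enumerate(order)}
    keyed = [tuple(code[c] for c in text[i:]) for i in range(len(text))]
    return sorted(range(len(text)), key=lambda i: keyed[i])


def naive_occurrences(text: str, q: str) -> list[int]:
    """All start offsets of q in text, by direct scan."""
    return [i for i in range(len(text) - len(q) + 1) if text[i : i + len(q)] == q]
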