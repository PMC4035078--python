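import pytest

from drrl import (
    canonical_vertebrate_order,
    reconstruct_slatus,
    samariscus_latus_order,
    table1_fixture,
)
from drrl.orders import GeneElement, GeneOrder


@pytest.fixture(scope="session")
def canon():
    return canonical_vertebrate_order()


@pytest.fixture(scope="session")
def slatus():
    return samariscus_latus_order()


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture(scope="session")
def stages():
    return dict(reconstruct_slatus())


def toy_order(n, with_cr=True, strands=None):
    """A linear-labelled circular toy order g1..gn (+ CR)."""
    els = [
        GeneElement(label=f"g{i}", element_class="CDS",
                    strand=(strands or {}).get(i, "H"))
        for i in range(1, n + 1)
    ]
    if with_cr:
        els.append(GeneElement(label="CR", element_class="CR", strand="H"))
    return GeneOrder(tuple(els))


@pytest.fixture
def toy6():
    return toy_order(6)
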