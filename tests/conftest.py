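import pytest

from polyfock import builtin_fixture, compile_model
from polyfock.fock import make_mode


@pytest.fixture(scope="session")
def homodimer4():
    return builtin_fixture("homodimer", 4)


@pytest.fixture(scope="session")
def homodimer4_compiled(homodimer4):
    return compile_model(homodimer4)


@pytest.fixture(scope="session")
def homopolymer3():
    return builtin_fixture("homopolymer", 3)


@pytest.fixture(scope="session")
def monomer20():
    return builtin_fixture("monomer", 20)


def chain_microstate(model, chains, rings=()):
    """Microstate with the given directed chains/rings over particle indices."""
    s = set()

    def link(u, v):
        s.add(make_mode(model, "a", (u,)))
        s.add(make_mode(model, "b", (v,)))
        s.add(make_mode(model, "J", (u, v)))

    for ch in chains:
        for i in ch:
            s.add(make_mode(model, "A", (i,)))
        for u, v in zip(ch, ch[1:]):
            link(u, v)
    for rg in rings:
        for i in rg:
            s.add(make_mode(model, "A", (i,)))
        for u, v in zip(rg, rg[1:]):
            link(u, v)
        link(rg[-1], rg[0])
    return frozenset(s)
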