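import pytest

from depthvar.treecore import build_classic, enumerate_shapes


@pytest.fixture(scope="session")
def shapes_by_n():
    """Memoized exhaustive shape lists (with labeled counts) for small n."""
    cache = {}

    def get(n):
        if n not in cache:
            cache[n] = list(enumerate_shapes(n))
        return cache[n]

    return get


@pytest.fixture(scope="session")
def comb():
    return lambda n: build_classic("comb", n)


@pytest.fixture(scope="session")
def balanced():
    return lambda n: build_classic("max_balanced", n)
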