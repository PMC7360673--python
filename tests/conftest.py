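import numpy as np
import pytest

from phaselock.source_space import SourceGrid, build_regular_grid


@pytest.fixture
def grid333() -> SourceGrid:
    """3x3x3 grid, 10 mm spacing, 27 sources."""
    return build_regular_grid(((0, 20), (0, 20), (0, 20)), 10)


@pytest.fixture
def grid_flat() -> SourceGrid:
    """5x5x1 flat grid, 10 mm spacing, 25 sources."""
    return build_regular_grid(((0, 40), (0, 40), (0, 0)), 10)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def brute_force_components(nodes: set[int], edges) -> list[frozenset]:
    """Flood-fill connected components over ``nodes`` using ``edges``."""
    nbr = {n: set() for n in nodes}
    for i, j in edges:
        if i in nodes and j in nodes:
            nbr[i].add(j)
            nbr[j].add(i)
    seen: set[int] = set()
    comps = []
    for start in nodes:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(nbr[u] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return comps
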