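import numpy as np
import pytest

import polyafilter as pf


@pytest.fixture
def fig1():
    """Worked-example star: hub A (k=3, s=4) with links w = 2, 1, 1."""
    return pf.fig1_fixture()


@pytest.fixture
def two_tier():
    """Heterogeneous core-periphery network for salience/optimality tests.

    A small heavy core (ring plus dominant chords between hubs) carries the
    shortest paths; peripheral nodes attach by unit-weight ties and one
    locally dominant weak link each.  Peripheral dominant links are
    significant only at small a and have low salience, core links stay
    significant and salient, so the optimality products peak at an interior
    reinforcement value.
    """
    rng = np.random.default_rng(23)
    n_hubs, n_per = 8, 36
    links = {}

    def add(u, v, w):
        key = (min(u, v), max(u, v))
        if u != v and key not in links:
            links[key] = w

    hubs = [f"h{i}" for i in range(n_hubs)]
    pers = [f"p{i:02d}" for i in range(n_per)]
    for i in range(n_hubs):
        add(hubs[i], hubs[(i + 1) % n_hubs], float(rng.integers(40, 90)))
    for i in range(n_hubs):
        add(hubs[i], hubs[(i + 3) % n_hubs], float(rng.integers(150, 400)))
    for p in pers:
        for h in rng.choice(n_hubs, size=3, replace=False):
            add(p, hubs[h], 1.0)
        q = pers[int(rng.integers(n_per))]
        if q != p:
            add(p, q, float(rng.integers(6, 12)))
    return pf.WeightedNetwork.from_links(
        [(u, v, w) for (u, v), w in links.items()], directed=False
    )


def write_edgelist(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return str(path)
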