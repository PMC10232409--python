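import numpy as np
import pytest

from connectotype import make_atlas, make_mesh


@pytest.fixture(scope="session")
def ico162():
    return make_mesh(162, "icosphere")


@pytest.fixture(scope="session")
def ico642():
    return make_mesh(642, "icosphere")


@pytest.fixture(scope="session")
def grid100():
    return make_mesh(100, "grid")


@pytest.fixture(scope="session")
def atlas162(ico162):
    return make_atlas(ico162, n_networks=6, n_rois=24, seed=1)


@pytest.fixture(scope="session")
def atlas642(ico642):
    return make_atlas(ico642, n_networks=18, n_rois=116, seed=1)


@pytest.fixture(scope="session")
def geo162(ico162):
    return ico162.geodesic_distances()


@pytest.fixture(scope="session")
def geo642(ico642):
    return ico642.geodesic_distances()


def flood_fill_components(neighbors, members):
    """Brute-force connected components of a vertex set (independent oracle)."""
    members = set(int(v) for v in np.atleast_1d(members))
    comps = []
    seen = set()
    for start in sorted(members):
        if start in seen:
            continue
        comp = {start}
        frontier = [start]
        while frontier:
            v = frontier.pop()
            for u in neighbors[v]:
                u = int(u)
                if u in members and u not in comp:
                    comp.add(u)
                    frontier.append(u)
        seen |= comp
        comps.append(comp)
    return comps
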