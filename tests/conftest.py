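import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_tissue():
    """One modest synthetic field with planted structures, shared read-only."""
    from acdkit.synthetic import TissueSpec, generate_epidermis

    spec = TissueSpec(field_width_um=180.0, field_height_um=180.0,
                      pixel_size_um=1.0, n_cells=100,
                      small_cell_fraction=0.1, planted_clusters=[(4, 2)],
                      stomata_fraction=0.1, planted_stomatal_pairs=2, seed=7)
    labels, table = generate_epidermis(spec)
    return spec, labels, table


def brute_force_components(small_ids, edges, min_size):
    """Independent connected-components oracle (breadth-first flood)."""
    small_ids = set(small_ids)
    neigh = {i: set() for i in small_ids}
    for a, b in edges:
        if a in small_ids and b in small_ids:
            neigh[a].add(b)
            neigh[b].add(a)
    seen, comps = set(), []
    for start in sorted(small_ids):
        if start in seen:
            continue
        comp, frontier = {start}, [start]
        while frontier:
            cur = frontier.pop()
            for nb in neigh[cur]:
                if nb not in comp:
                    comp.add(nb)
                    frontier.append(nb)
        seen |= comp
        comps.append(comp)
    return sorted((c for c in comps if len(c) >= min_size), key=min)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
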