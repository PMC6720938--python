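import random

import pytest

from phytonet.chem_io import AROMATIC, MolecularGraph
from phytonet.synthetic_data import SimulationConfig, gen_molecules


def chain(elements, orders=None):
    """Linear molecule helper: elements bonded i-(i+1)."""
    n = len(elements)
    orders = orders or [1.0] * (n - 1)
    return MolecularGraph(
        atoms=[(e, 0) for e in elements],
        bonds=[(i, i + 1, orders[i]) for i in range(n - 1)],
    )


@pytest.fixture
def ethanol():
    return chain(["C", "C", "O"])


@pytest.fixture
def benzene():
    return MolecularGraph(
        atoms=[("C", 0)] * 6,
        bonds=[(i, (i + 1) % 6, AROMATIC) for i in range(6)],
    )


@pytest.fixture
def glycine():
    # N-C-C(=O)-O
    return MolecularGraph(
        atoms=[("N", 0), ("C", 0), ("C", 0), ("O", 0), ("O", 0)],
        bonds=[(0, 1, 1.0), (1, 2, 1.0), (2, 3, 2.0), (2, 4, 1.0)],
    )


def random_connected_graph(rng: random.Random, n: int) -> MolecularGraph:
    """Random tree of carbons plus optional extra edges (graph-shape tests)."""
    bonds = []
    for k in range(1, n):
        bonds.append((rng.randrange(k), k, 1.0))
    existing = {(min(i, j), max(i, j)) for i, j, _ in bonds}
    for _ in range(rng.randint(0, n // 3)):
        i, j = rng.sample(range(n), 2)
        key = (min(i, j), max(i, j))
        if key not in existing:
            existing.add(key)
            bonds.append((key[0], key[1], 1.0))
    return MolecularGraph(atoms=[("C", 0)] * n, bonds=bonds)


@pytest.fixture(scope="session")
def default_molecules():
    """One shared batch of generated molecules for property tests."""
    return gen_molecules(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def synthetic_bundle(tmp_path_factory):
    """A default synthetic input bundle on disk plus its ground truth."""
    from phytonet.synthetic_data import emit_bundle

    outdir = tmp_path_factory.mktemp("bundle")
    truth = emit_bundle(SimulationConfig(seed=11), outdir)
    return outdir, truth
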