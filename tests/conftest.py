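import numpy as np
import pytest

from sbcg2.model import AngleParam, BondParam, CGBead, CGModel, ParameterSet
from sbcg2.synthetic_fixtures import FixtureSpec, make_chain_model, make_structure


@pytest.fixture
def blob300():
    """300-atom protein-like blob, fixed seed."""
    return make_structure(FixtureSpec(n_atoms=300, seed=11))


@pytest.fixture
def small_blob():
    return make_structure(FixtureSpec(n_atoms=60, seed=5))


@pytest.fixture
def chain5():
    """5-bead chain model with a full harmonic parameter set."""
    model = make_chain_model(5)
    params = ParameterSet(
        bonds={b: BondParam(k=5.0 + 2.0 * i, b0=5.0)
               for i, b in enumerate(model.bonds)},
        angles={a: AngleParam(k=10.0 + 3.0 * i, theta0=2.1)
                for i, a in enumerate(model.angles)},
    )
    return model, params


@pytest.fixture
def one_bond():
    """Minimal 1-bond CG system (K = 5 kcal/mol/A^2, b0 = 5 A)."""
    beads = [CGBead(position=[0.0, 0.0, 0.0], mass=50.0, charge=0.0, radius=2.0),
             CGBead(position=[5.0, 0.0, 0.0], mass=50.0, charge=0.0, radius=2.0)]
    model = CGModel(beads=beads, bonds=[(0, 1)])
    params = ParameterSet(bonds={(0, 1): BondParam(k=5.0, b0=5.0)})
    return model, params


def delaunay_edges(points):
    """Brute-force Delaunay adjacency of a 3-D point set (test oracle)."""
    from scipy.spatial import Delaunay
    tri = Delaunay(points)
    edges = set()
    for simplex in tri.simplices:
        for a in range(len(simplex)):
            for b in range(a + 1, len(simplex)):
                i, j = sorted((int(simplex[a]), int(simplex[b])))
                edges.add((i, j))
    return edges
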