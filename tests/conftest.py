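from pathlib import Path

import numpy as np
import pytest

from llcmda import (
    DiseaseDAG,
    read_associations,
    read_similarity,
    standard_fixture,
)

FIXTURE_DIR = Path(__file__).parent / "fixtures"


@pytest.fixture(scope="session")
def fixture_data():
    """The standard planted-block fixture (20 miRNAs x 15 diseases, seed 7)."""
    return standard_fixture()


@pytest.fixture(scope="session")
def committed_fixture():
    """Same fixture, loaded from the committed TSV files."""
    assoc = read_associations(FIXTURE_DIR / "assoc.tsv", format="dense")
    fms = read_similarity(FIXTURE_DIR / "fms.tsv", kind="functional")
    dss = read_similarity(FIXTURE_DIR / "dss.tsv", kind="semantic")
    return assoc, fms, dss


def chain_dag():
    """Disease A with parent p and grandparent g (a 3-term chain)."""
    return DiseaseDAG("A", nodes={"A", "p", "g"}, edges={("A", "p"), ("p", "g")})


def random_dag(rng: np.random.Generator, n_nodes: int) -> DiseaseDAG:
    """Random rooted ancestor DAG: node k picks >=1 parents among 0..k-1.

    Node 0 is the disease term; every other node is an ancestor reachable
    from it, so the DAG is valid by construction.
    """
    names = [f"t{k}" for k in range(n_nodes)]
    edges = set()
    for k in range(1, n_nodes):
        # ancestor t_k is a parent of >=1 lower-index terms, so t0 reaches
        # every node by induction (child -> parent edges point upward)
        children = rng.choice(k, size=int(rng.integers(1, k + 1)), replace=False)
        for c in children:
            edges.add((names[int(c)], names[k]))
    return DiseaseDAG("t0", nodes=set(names), edges=edges)
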