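import numpy as np
import pandas as pd
import pytest

from aldhdrivers.curation import build_dataset
from aldhdrivers.pipeline import read_fasta
from aldhdrivers.structure_features import Structure
from aldhdrivers.synthetic import SyntheticConfig, generate_fixture, generate_toy_structure


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    root = tmp_path_factory.mktemp("fixture")
    return generate_fixture(SyntheticConfig(), root, seed=11)


@pytest.fixture(scope="session")
def curated_dataset(fixture_bundle):
    catalogs = {
        name: pd.read_csv(path, sep="\t")
        for name, path in fixture_bundle.catalogs.items()
    }
    sequences = read_fasta(fixture_bundle.fasta)
    return build_dataset(catalogs, sequences)


@pytest.fixture(scope="session")
def helix():
    return generate_toy_structure(20, seed=7)


def make_structure(xyz, names=None, resnames=None, elements=None, resis=None,
                   chains=None):
    """Hand-rolled Structure for small geometric test cases."""
    xyz = np.asarray(xyz, dtype=float)
    n = len(xyz)
    names = names or ["CA"] * n
    resnames = resnames or ["ALA"] * n
    elements = elements or [nm[0] for nm in names]
    resis = resis if resis is not None else list(range(1, n + 1))
    chains = chains or ["A"] * n
    from aldhdrivers.tables import DEFAULT_VDW_RADIUS, VDW_RADII

    return Structure(
        chain=np.array(chains, dtype=object),
        resi=np.array(resis, dtype=int),
        resname=np.array(resnames, dtype=object),
        atom_name=np.array(names, dtype=object),
        element=np.array(elements, dtype=object),
        xyz=xyz,
        radius=np.array([VDW_RADII.get(e, DEFAULT_VDW_RADIUS) for e in elements]),
    )
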