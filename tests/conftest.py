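import numpy as np
import pytest
from hypothesis import settings

from korscreen import chem, fixtures

settings.register_profile("suite", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("suite")


SMALL_SPEC = fixtures.FixtureSpec(seed=11, n_actives=6, decoys_per_active=5, universe_depth=2)


@pytest.fixture(scope="session")
def small_spec():
    return SMALL_SPEC


@pytest.fixture(scope="session")
def small_fixture():
    """6 actives + a shallow decoy universe; shared across the suite."""
    return fixtures.make_compound_fixture(SMALL_SPEC)


@pytest.fixture(scope="session")
def reduced_query():
    return fixtures.reference_query(SMALL_SPEC)


@pytest.fixture(scope="session")
def full_query():
    return fixtures.reference_query(SMALL_SPEC, reduced=False)


@pytest.fixture(scope="session")
def template():
    return fixtures.template_active(SMALL_SPEC)


@pytest.fixture()
def mol_3d():
    """A small rigid molecule with one embedded conformer."""

    def _make(smiles: str, name: str = "mol", seed: int = 7):
        rec = chem.from_smiles(name, smiles)
        chem.embed_conformers(rec, 1, seed)
        return rec

    return _make


def rotate_record(rec, rotation, translation):
    """Copy of a record with its first conformer rigidly moved."""
    from rdkit import Chem as _Chem

    mol = _Chem.Mol(rec.mol)
    conf = mol.GetConformer(0)
    coords = rec.conformer_coords(0) @ np.asarray(rotation).T + np.asarray(translation)
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, xyz.tolist())
    return chem.MoleculeRecord(rec.id + "_moved", mol, dict(rec.descriptors), dict(rec.flags))
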