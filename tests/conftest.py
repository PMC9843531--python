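"""Shared fixtures: all test data is generated programmatically."""

import pytest

from navscreen.chem import parse_molecule
from navscreen.curation import MoleculeRecord, RawRecord


@pytest.fixture(scope="session")
def small_library():
    """A tiny curated-like record set: 6 sulfonamide actives, 6 inactives."""
    actives = [
        "NS(=O)(=O)c1ccccc1", "NS(=O)(=O)c1ccc(C)cc1",
        "NS(=O)(=O)c1ccc(Cl)cc1", "NS(=O)(=O)c1ccc(O)cc1",
        "NS(=O)(=O)c1ccc(N)cc1", "NS(=O)(=O)c1ccc(F)cc1",
    ]
    inactives = [
        "c1ccccc1", "CCO", "CCCCCC", "c1ccncc1", "CC(=O)O", "CCN(CC)CC",
    ]
    records = []
    for i, smi in enumerate(actives):
        records.append(MoleculeRecord(mol=parse_molecule(smi, f"act{i}"),
                                      activity_nM=100.0, label=1))
    for i, smi in enumerate(inactives):
        records.append(MoleculeRecord(mol=parse_molecule(smi, f"inact{i}"),
                                      activity_nM=100_000.0, label=0))
    return records


@pytest.fixture(scope="session")
def default_library():
    """One default synthetic library, generated once per session."""
    from navscreen.synthetic import default_library_spec, generate_library

    return generate_library(default_library_spec(seed=1))


@pytest.fixture(scope="session")
def curated_default_library(default_library):
    from navscreen.curation import CurationConfig, curate

    raw = [RawRecord(r.mol.id, r.mol.smiles_canonical, r.activity_nM, r.source)
           for r in default_library]
    curated, _ = curate(raw, CurationConfig())
    meta = {r.mol.id: r for r in default_library}
    for rec in curated:
        origin = meta.get(rec.mol.id)
        if origin is not None:
            rec.family, rec.planted = origin.family, origin.planted
    return curated
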