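"""Chemistry substrate: parsing, descriptors, fingerprints, similarity, SMARTS.

Everything downstream (curation, clustering, modeling, alert mining) consumes
molecules through this module, so the contracts here are deliberately small:
canonical SMILES as the identity of a structure, seven scalar descriptors, six
fixed-length fingerprint families plus ECFP4, and set-based Tanimoto.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import FrozenSet

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, MACCSkeys, rdFingerprintGenerator
from rdkit.Chem.EState import Fingerprinter as _EStateFingerprinter

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "Molecule",
    "DescriptorSet",
    "Fingerprint",
    "FINGERPRINT_LENGTHS",
    "MoleculeParseError",
    "parse_molecule",
    "compute_descriptors",
    "compute_fingerprint",
    "fingerprint_matrix",
    "tanimoto",
    "matches_smarts",
]


class MoleculeParseError(ValueError):
    """Raised when a SMILES (or SMARTS) string cannot be parsed."""


# Static atomic polarizabilities (CRC Handbook, 10^-24 cm^3) for the apol
# descriptor: the sum over all atoms, implicit hydrogens included.
_ATOMIC_POLARIZABILITY = {
    1: 0.666793, 5: 3.03, 6: 1.76, 7: 1.10, 8: 0.802, 9: 0.557,
    14: 5.38, 15: 3.63, 16: 2.90, 17: 2.18, 33: 4.31, 34: 3.77,
    35: 3.05, 53: 5.35,
}
_DEFAULT_POLARIZABILITY = 1.76  # fall back to carbon for exotic elements

#: fixed bit-length contract per fingerprint family
FINGERPRINT_LENGTHS = {
    "cdk_path": 1024,
    "estate": 79,
    "extended_path": 1024,
    "graph_only": 1024,
    "maccs": 166,
    "pubchem_keys": 881,
    "ecfp4": 2048,
}

#: the six families used in the classification model grid (ECFP4 is reserved
#: for similarity, clustering and alert mining)
MODEL_FAMILIES = ("cdk_path", "estate", "extended_path", "graph_only", "maccs", "pubchem_keys")


@dataclass(frozen=True)
class Molecule:
    """A parsed compound with canonical-SMILES identity.

    ``n_atoms`` counts all atoms including implicit hydrogens by default
    (the convention used by the atom-count curation filter); heavy-atom
    counts are available via :func:`parse_molecule`'s ``heavy_atoms_only``.
    """

    id: str
    smiles_canonical: str
    n_atoms: int

    def rdmol(self) -> Chem.Mol:
        return _mol_from_canonical(self.smiles_canonical)


@dataclass(frozen=True)
class DescriptorSet:
    """The seven physchem descriptors used in curation and group comparison."""

    mw: float        # molecular weight, g/mol
    apol: float      # summed atomic polarizability (unitless sum)
    alogp: float     # Crippen logP, log units
    nhbdon: int      # H-bond donors
    nhbacc: int      # H-bond acceptors
    nrot: int        # rotatable bonds
    tpsa: float      # topological polar surface area, A^2


@dataclass(frozen=True)
class Fingerprint:
    family: str
    n_bits: int
    bits: FrozenSet[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.n_bits):
            raise ValueError(f"bit index out of range for {self.family}/{self.n_bits}")

    def to_array(self) -> np.ndarray:
        vec = np.zeros(self.n_bits, dtype=np.uint8)
        if self.bits:
            vec[sorted(self.bits)] = 1
        return vec


@lru_cache(maxsize=100_000)
def _mol_from_canonical(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # pragma: no cover - canonical strings always re-parse
        raise MoleculeParseError(f"canonical SMILES failed to re-parse: {smiles!r}")
    return mol


def parse_molecule(smiles: str, mol_id: str = "", *, heavy_atoms_only: bool = False) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule` with canonical identity.

    Raises :class:`MoleculeParseError` naming ``mol_id`` on failure so curation
    logs can point at the offending input row.
    """
    if not smiles or not smiles.strip():
        raise MoleculeParseError(f"empty SMILES for molecule {mol_id!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(f"unparseable SMILES for molecule {mol_id!r}: {smiles!r}")
    canonical = Chem.MolToSmiles(mol)
    n_heavy = mol.GetNumAtoms()
    n_atoms = n_heavy if heavy_atoms_only else n_heavy + sum(
        a.GetTotalNumHs() for a in mol.GetAtoms()
    )
    return Molecule(id=mol_id or canonical, smiles_canonical=canonical, n_atoms=n_atoms)


def compute_descriptors(mol: Molecule) -> DescriptorSet:
    m = mol.rdmol()
    apol = sum(
        _ATOMIC_POLARIZABILITY.get(a.GetAtomicNum(), _DEFAULT_POLARIZABILITY)
        + a.GetTotalNumHs() * _ATOMIC_POLARIZABILITY[1]
        for a in m.GetAtoms()
    )
    return DescriptorSet(
        mw=Descriptors.MolWt(m),
        apol=apol,
        alogp=Crippen.MolLogP(m),
        nhbdon=Lipinski.NumHDonors(m),
        nhbacc=Lipinski.NumHAcceptors(m),
        nrot=Lipinski.NumRotatableBonds(m),
        tpsa=Descriptors.TPSA(m),
    )


# Fingerprint generators are stateless and shared. The path-hashed families
# differ in their path depth / branching / bond-order settings so that the six
# model families probe genuinely different views of the molecular graph:
#   cdk_path       linear paths to depth 5
#   extended_path  branched paths to depth 7 (ring-aware superset)
#   graph_only     bond-order-blind paths (connectivity only)
#   pubchem_keys   hashed radius-1 circular environments folded to 881 bits
#   maccs          the 166 MACCS structural keys
#   estate         the 79 E-state atom-type bins, binarized
@lru_cache(maxsize=None)
def _generator(family: str):
    if family == "cdk_path":
        return rdFingerprintGenerator.GetRDKitFPGenerator(
            maxPath=5, fpSize=1024, branchedPaths=False)
    if family == "extended_path":
        return rdFingerprintGenerator.GetRDKitFPGenerator(
            maxPath=7, fpSize=1024, branchedPaths=True)
    if family == "graph_only":
        return rdFingerprintGenerator.GetRDKitFPGenerator(
            maxPath=7, fpSize=1024, useBondOrder=False)
    if family == "pubchem_keys":
        return rdFingerprintGenerator.GetMorganGenerator(radius=1, fpSize=881)
    if family == "ecfp4":
        return rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
    raise KeyError(family)


def compute_fingerprint(mol: Molecule, family: str) -> Fingerprint:
    """Compute one fingerprint family for one molecule (deterministic)."""
    if family not in FINGERPRINT_LENGTHS:
        raise KeyError(
            f"unknown fingerprint family {family!r}; expected one of "
            f"{sorted(FINGERPRINT_LENGTHS)}")
    m = mol.rdmol()
    n_bits = FINGERPRINT_LENGTHS[family]
    if family == "maccs":
        # RDKit emits 167 bits with index 0 permanently unset; shift to 166.
        raw = MACCSkeys.GenMACCSKeys(m)
        bits = frozenset(i - 1 for i in raw.GetOnBits())
    elif family == "estate":
        counts, _sums = _EStateFingerprinter.FingerprintMol(m)
        bits = frozenset(int(i) for i in np.nonzero(counts)[0])
    else:
        bits = frozenset(_generator(family).GetFingerprint(m).GetOnBits())
    return Fingerprint(family=family, n_bits=n_bits, bits=bits)


def fingerprint_matrix(mols, family: str) -> np.ndarray:
    """Stacked 0/1 feature matrix (n_molecules x n_bits) for a family."""
    return np.vstack([compute_fingerprint(m, family).to_array() for m in mols])


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |A∩B| / |A∪B| over set bits.

    Two all-zero fingerprints compare as 1.0 (reflexivity convention for the
    0/0 case) with a warning, since an empty bit set carries no information.
    """
    if a.family != b.family:
        raise ValueError(f"fingerprint family mismatch: {a.family} vs {b.family}")
    union = len(a.bits | b.bits)
    if union == 0:
        logger.warning("Tanimoto of two empty %s fingerprints; returning 1.0", a.family)
        return 1.0
    return len(a.bits & b.bits) / union


@lru_cache(maxsize=1024)
def _smarts(pattern: str) -> Chem.Mol:
    query = Chem.MolFromSmarts(pattern)
    if query is None:
        raise MoleculeParseError(f"invalid SMARTS pattern: {pattern!r}")
    return query


def matches_smarts(mol: Molecule, pattern: str) -> bool:
    """True iff ``pattern`` has at least one substructure embedding in ``mol``."""
    return mol.rdmol().HasSubstructMatch(_smarts(pattern))
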