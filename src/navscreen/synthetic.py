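"""Synthetic SMILES libraries with planted, known ground truth.

Real channel-inhibitor bioactivity data has a characteristic statistical
structure: families of near-duplicate analogs published together, lognormal
IC50 values straddling the activity threshold, a recurring "privileged"
fragment enriched among actives, and a broad set of unrelated decoys. This
module generates libraries with exactly that structure so the whole pipeline
— curation, clustering undersampling, model grid, alert mining — can be
exercised hermetically against known truth.

Construction: each analog family is one drug-like scaffold carrying three
attachment points zipped (via map-numbered dummy atoms) with

* ``[*:1]`` — a member-specific small substituent at the end of a linker
  built into the scaffold, so members of a family differ by only a few atom
  environments (intra-family ECFP4 Tanimoto > 0.85 by construction);
* ``[*:2]`` — an aromatic site that receives either the planted
  methanesulfonamide-style fragment ``S(N)(=O)=O`` or a small cap, decided
  per family for analog families and per molecule for decoys;
* ``[*:3]`` — a family-identity substituent, so families sharing a scaffold
  remain distinct compounds.

IC50 values are lognormal per class (family median times member-level
jitter), so threshold labeling is imperfect in a controlled way.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem

from .chem import compute_fingerprint, parse_molecule, tanimoto
from .curation import MoleculeRecord, assign_label

logger = logging.getLogger(__name__)

#: planted fragment (attaches to an aromatic carbon) and the SMARTS that
#: detects it; nothing else in the vocabularies contains a sulfonamide
PLANTED_FRAGMENT = "[*:2]S(N)(=O)=O"
PLANTED_SMARTS = "S(=O)(=O)N"

# Family scaffolds: ~24-27 heavy atoms (enough shared atom environments that
# single-substituent analogs stay above 0.85 ECFP4 Tanimoto), member linker
# ending in [*:1], aromatic [*:2], family-identity site [*:3]. Sizes and
# heteroatom budgets keep every vocabulary combination Lipinski-compliant.
FAMILY_SCAFFOLDS = [
    "[*:1]CCOc1ccc(-c2nc3cc([*:2])ccc3o2)cc1OCC(=O)N([*:3])C",
    "[*:1]CCOc1cccc(C(=O)N2CCc3cc([*:2])ccc3C2COC(=O)[*:3])c1",
    "[*:1]CCOc1ccc2nc(N(C)C(C)=O)c(Cc3ccc([*:2])cc3[*:3])nc2c1",
    "[*:1]CCOc1ccc(-n2cnc3cc([*:2])ccc32)cc1OCC(=O)N(C)[*:3]",
    "[*:1]CCOc1ccc(CNC(=O)c2ccc(-n3cccn3)cc2[*:3])cc1[*:2]",
    "[*:1]CCOc1ccc2c(c1)CCN(C(=O)c1cc([*:2])ccc1OC[*:3])C2",
    "[*:1]CCOc1ccc(N2CCN(C(=O)c3cc([*:2])ccc3OC[*:3])CC2)cc1",
    "[*:1]CCn1cc(C(=O)Nc2cc([*:2])ccc2OC[*:3])c(=O)c2ccccc21",
    "[*:1]CCOc1ccc(CNC(=O)C2CCN(c3cc([*:2])ccc3[*:3])CC2)cc1",
    "[*:1]CCOc1ccc(-c2nnc(SCC(=O)N(C)[*:3])n2C)cc1[*:2]",
    "[*:1]CCOc1cc([*:2])ccc1-c1nc2cc(C(=O)N(C)[*:3])ccc2[nH]1",
    "[*:1]CCOc1ccc(-c2noc(Cc3cc([*:2])ccc3OC[*:3])n2)cn1",
    "[*:1]CCOc1ccc(C2CC(=O)N(Cc3cc([*:2])ccc3OC[*:3])C2)cn1",
    "[*:1]CCn1cc(C(=O)Nc2cc([*:2])ccc2OCC(=O)N(C)[*:3])cn1",
    "[*:1]CCOc1ccc(CNC(=O)c2cc([*:2])ccc2OCC(=O)N(C)[*:3])cc1",
]

#: member-level substituents: small terminal edits at the linker end
MEMBER_SUBSTITUENTS = [
    "[*:1]C", "[*:1]O", "[*:1]N", "[*:1]F",
    "[*:1]Cl", "[*:1]CC", "[*:1]CO", "[*:1]CN",
]

#: family-identity substituents (kept light so no combination breaks MW 500)
FAMILY_SUBSTITUENTS = [
    "[*:3]C", "[*:3]F", "[*:3]Cl", "[*:3]O",
    "[*:3]N", "[*:3]CC", "[*:3]OC", "[*:3]CO",
]

#: aromatic caps used when the planted fragment is absent; sized like the
#: fragment so planted and unplanted families have comparable shared context
CAPS = ["[*:2]OCC", "[*:2]N(C)C", "[*:2]CCO", "[*:2]OC(C)C"]

# Decoy scaffolds: deliberately heterogeneous cores and sizes; [*:1] takes a
# member substituent, [*:2] the cap or (rarely) the planted fragment.
DECOY_SCAFFOLDS = [
    "[*:1]Cc1ccc([*:2])cc1",
    "[*:1]CC(=O)Nc1ccc([*:2])cc1",
    "[*:1]Cc1noc(C)c1-c1ccc([*:2])cc1",
    "[*:1]CN1CCOC(c2ccc([*:2])cc2)C1",
    "[*:1]Cc1ccc(O)c(CNCc2ccc([*:2])cc2)c1",
    "[*:1]CC1CCN(c2ncccc2[*:2])CC1",
    "[*:1]Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "[*:1]CC(O)COc1ccc([*:2])cc1",
    "[*:1]Cc1cc(=O)oc2cc([*:2])ccc12",
    "[*:1]CC(=O)N1CCCC1c1ccc([*:2])cc1",
    "[*:1]Cc1nc2ccccc2s1",
    "[*:1]CCOC(=O)c1ccc([*:2])nc1",
    "[*:1]Cc1ccc([*:2])c2ccccc12",
    "[*:1]CN(C)C(=O)Cn1nnc(-c2ccc([*:2])cc2)n1",
    "[*:1]Cc1ccco1",
    "[*:1]CC(C)NCC(O)c1ccc([*:2])cc1",
    "[*:1]Cc1cnn(-c2ccc([*:2])cc2)c1",
    "[*:1]CNC(=O)C1CCC([*:2])CC1",
    "[*:1]Cc1ncc(CO)c(C)c1O",
    "[*:1]CC1COc2cc([*:2])ccc2O1",
    "[*:1]Cc1ccc2[nH]c(C)cc2c1[*:2]",
    "[*:1]COc1cc([*:2])ccc1OC",
    "[*:1]CC(=O)c1ccc([*:2])o1",
    "[*:1]CN1CCCC1=Nc1ccc([*:2])cc1",
]

# Decoy scaffolds without an explicit [*:2] site are capped automatically.
_NO_SITE2 = {s for s in DECOY_SCAFFOLDS if "[*:2]" not in s}


class GenerationError(RuntimeError):
    """Raised when a spec cannot produce a parseable, distinct molecule."""


@dataclass(frozen=True)
class LibrarySpec:
    """Parameters of one synthetic library; same seed, same library."""

    n_active_families: int = 40
    n_inactive_families: int = 20
    family_size_mean: float = 5.0
    n_decoys: int = 150
    enrichment_active: float = 0.9
    enrichment_inactive: float = 0.1
    active_ic50_median_nM: float = 3_000.0
    active_ic50_sigma: float = 1.0       # sigma of ln(family median)
    inactive_ic50_median_nM: float = 150_000.0
    inactive_ic50_sigma: float = 0.8
    member_ic50_sigma: float = 0.3       # member-level assay jitter
    threshold_nM: float = 30_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.enrichment_active, self.enrichment_inactive):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("enrichment fractions must lie in [0, 1]")
        if min(self.n_active_families, self.n_inactive_families, self.n_decoys) < 0:
            raise ValueError("counts must be non-negative")
        if self.family_size_mean < 2:
            raise ValueError("family_size_mean must be >= 2")


def default_library_spec(seed: int = 0) -> LibrarySpec:
    """The study conditions every analysis stage is exercised under."""
    return LibrarySpec(seed=seed)


def benchmark_library_spec(seed: int = 0) -> LibrarySpec:
    """Separable classification benchmark: ~800 molecules, planted fragment
    present in every active family and absent elsewhere, IC50 distributions
    well clear of the threshold."""
    return LibrarySpec(
        n_active_families=78, n_inactive_families=39, n_decoys=200,
        enrichment_active=1.0, enrichment_inactive=0.0,
        active_ic50_median_nM=1_000.0, active_ic50_sigma=0.6,
        inactive_ic50_median_nM=400_000.0, inactive_ic50_sigma=0.6,
        seed=seed,
    )


def alert_library_spec(seed: int = 0) -> LibrarySpec:
    """Alert-mining benchmark: ~400 molecules, enrichment 0.9 vs 0.1."""
    return LibrarySpec(
        n_active_families=36, n_inactive_families=20, n_decoys=120,
        enrichment_active=0.9, enrichment_inactive=0.1,
        seed=seed,
    )


def _zip_smiles(pieces: Sequence[str]) -> str:
    mols = []
    for smi in pieces:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise GenerationError(f"vocabulary SMILES failed to parse: {smi!r}")
        mols.append(mol)
    combined = mols[0]
    for mol in mols[1:]:
        combined = Chem.CombineMols(combined, mol)
    zipped = Chem.molzip(combined)
    Chem.SanitizeMol(zipped)
    return Chem.MolToSmiles(zipped)


def _lognormal_nM(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(median * np.exp(sigma * rng.standard_normal()))


def generate_library(spec: LibrarySpec) -> List[MoleculeRecord]:
    """Generate one labeled library; deterministic for a given spec."""
    rng = np.random.default_rng(spec.seed)
    records: List[MoleculeRecord] = []
    seen: set[str] = set()

    # assign each family a distinct (scaffold, identity-substituent) pair
    n_families = spec.n_active_families + spec.n_inactive_families
    combos = list(itertools.product(range(len(FAMILY_SCAFFOLDS)),
                                    range(len(FAMILY_SUBSTITUENTS))))
    if n_families > len(combos):
        raise GenerationError(
            f"at most {len(combos)} distinct families supported, "
            f"{n_families} requested")
    rng.shuffle(combos)

    # plant the fragment in an exact quota of families per class so the
    # realized enrichment matches the specified fractions
    def _quota_flags(n: int, fraction: float) -> np.ndarray:
        flags = np.zeros(n, dtype=bool)
        flags[: int(round(fraction * n))] = True
        rng.shuffle(flags)
        return flags

    planted_active = _quota_flags(spec.n_active_families, spec.enrichment_active)
    planted_inactive = _quota_flags(spec.n_inactive_families, spec.enrichment_inactive)

    for fam_idx in range(n_families):
        active_family = fam_idx < spec.n_active_families
        scaffold_idx, identity_idx = combos[fam_idx]
        scaffold = FAMILY_SCAFFOLDS[scaffold_idx]
        identity = FAMILY_SUBSTITUENTS[identity_idx]
        planted = bool(planted_active[fam_idx] if active_family
                       else planted_inactive[fam_idx - spec.n_active_families])
        site2 = PLANTED_FRAGMENT if planted else CAPS[int(rng.integers(len(CAPS)))]
        median, sigma = (
            (spec.active_ic50_median_nM, spec.active_ic50_sigma) if active_family
            else (spec.inactive_ic50_median_nM, spec.inactive_ic50_sigma))
        family_median = _lognormal_nM(rng, median, sigma)

        size = max(2, int(rng.poisson(spec.family_size_mean)))
        size = min(size, len(MEMBER_SUBSTITUENTS))
        member_subs = rng.choice(len(MEMBER_SUBSTITUENTS), size=size, replace=False)
        family_name = f"fam{fam_idx:03d}"
        for member_no, sub_idx in enumerate(member_subs):
            smiles = _zip_smiles([scaffold, MEMBER_SUBSTITUENTS[sub_idx],
                                  site2, identity])
            if smiles in seen:  # pragma: no cover - distinct by construction
                continue
            seen.add(smiles)
            ic50 = _lognormal_nM(rng, family_median, spec.member_ic50_sigma)
            mol = parse_molecule(smiles, f"{family_name}_m{member_no}")
            records.append(MoleculeRecord(
                mol=mol, activity_nM=ic50,
                label=assign_label(ic50, spec.threshold_nM),
                source="assay", family=family_name, planted=planted))

    # structurally diverse decoys, always inactive, planted per molecule
    attempts = 0
    n_made = 0
    while n_made < spec.n_decoys:
        attempts += 1
        if attempts > 50 * max(spec.n_decoys, 1):
            raise GenerationError("could not generate enough distinct decoys")
        scaffold = DECOY_SCAFFOLDS[int(rng.integers(len(DECOY_SCAFFOLDS)))]
        sub = MEMBER_SUBSTITUENTS[int(rng.integers(len(MEMBER_SUBSTITUENTS)))]
        planted = bool(rng.random() < spec.enrichment_inactive)
        pieces = [scaffold, sub]
        if scaffold not in _NO_SITE2:
            pieces.append(PLANTED_FRAGMENT if planted
                          else CAPS[int(rng.integers(len(CAPS)))])
        else:
            planted = False
        smiles = _zip_smiles(pieces)
        if smiles in seen:
            continue
        seen.add(smiles)
        mol = parse_molecule(smiles, f"dec{n_made:03d}")
        records.append(MoleculeRecord(mol=mol, activity_nM=None, label=0,
                                      source="decoy", family=None,
                                      planted=planted))
        n_made += 1

    n_active = sum(r.label for r in records)
    logger.info("generated library: %d molecules (%d active, %d families, %d decoys)",
                len(records), n_active, n_families, spec.n_decoys)
    return records


def family_structure_check(records: Sequence[MoleculeRecord],
                           max_inter_pairs: int = 20_000,
                           seed: int = 0,
                           ) -> Tuple[Optional[float], Optional[float]]:
    """Mean intra-family and inter-family ECFP4 Tanimoto similarity.

    Inter-family pairs are subsampled (deterministically) when numerous.
    Returns (intra, inter); either is None when undefined (no family with
    two members / fewer than two families).
    """
    by_family: dict[str, list] = {}
    for rec in records:
        if rec.family is not None:
            by_family.setdefault(rec.family, []).append(
                compute_fingerprint(rec.mol, "ecfp4"))

    intra_vals: List[float] = []
    for fps in by_family.values():
        for i in range(len(fps)):
            for j in range(i + 1, len(fps)):
                intra_vals.append(tanimoto(fps[i], fps[j]))

    families = sorted(by_family)
    inter_pairs = [(a, b) for i, a in enumerate(families) for b in families[i + 1:]]
    rng = np.random.default_rng(seed)
    inter_vals: List[float] = []
    for fam_a, fam_b in inter_pairs:
        for fp_a in by_family[fam_a]:
            for fp_b in by_family[fam_b]:
                inter_vals.append(tanimoto(fp_a, fp_b))
    if len(inter_vals) > max_inter_pairs:
        idx = rng.choice(len(inter_vals), size=max_inter_pairs, replace=False)
        inter_vals = [inter_vals[i] for i in idx]

    intra = float(np.mean(intra_vals)) if intra_vals else None
    inter = float(np.mean(inter_vals)) if inter_vals else None
    return intra, inter
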