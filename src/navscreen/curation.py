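"""Library curation: activity labeling, deduplication, drug-likeness funnel.

The funnel mirrors a standard bioactivity-data preparation workflow: parse and
canonicalize every structure, collapse duplicate structures to their median
assay value, assign binary labels against an activity threshold, then keep
only drug-like compounds (atom-count cap plus Lipinski's rule of five).
Random decoy molecules enter the same drug-likeness filter and are labeled
inactive. Every stage records its in/out/removed counts.
"""

from __future__ import annotations

import logging
import statistics
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .chem import (
    DescriptorSet,
    Molecule,
    MoleculeParseError,
    compute_descriptors,
    parse_molecule,
)

logger = logging.getLogger(__name__)

#: threshold dividing actives from inactives (IC50, nM)
DEFAULT_THRESHOLD_NM = 30_000.0

#: descriptors compared between the positive and negative classes
COMPARED_DESCRIPTORS = ("mw", "apol", "alogp", "nhbdon", "nrot", "nhbacc")


class CurationError(RuntimeError):
    """Raised when curation empties the library; carries the funnel log."""

    def __init__(self, message: str, log: "CurationLog"):
        super().__init__(f"{message}\n{log}")
        self.log = log


@dataclass
class RawRecord:
    """One input row before parsing: id, SMILES, optional assay value, source."""

    id: str
    smiles: str
    activity_nM: Optional[float] = None
    source: str = "assay"


@dataclass
class MoleculeRecord:
    """A curated compound: structure, activity, binary label, provenance."""

    mol: Molecule
    activity_nM: Optional[float]
    label: int
    source: str = "assay"
    family: Optional[str] = None   # analog-family tag (synthetic libraries)
    planted: bool = False          # carries the planted fragment (synthetic)

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {self.label}")
        if self.source == "assay" and self.activity_nM is None:
            raise ValueError(f"assay record {self.mol.id} lacks an activity")
        if self.source == "decoy" and self.label != 0:
            raise ValueError(f"decoy record {self.mol.id} must be labeled 0")


@dataclass
class CurationLog:
    """Ordered per-stage funnel counts; n_out = n_in - n_removed throughout."""

    stages: List[Tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_out: int) -> None:
        self.stages.append((stage, n_in, n_out, n_in - n_out))
        logger.info("curation stage %-16s %5d -> %5d (removed %d)",
                    stage, n_in, n_out, n_in - n_out)

    def __str__(self) -> str:
        lines = [f"{s:<18} in={a:>6} out={b:>6} removed={c:>6}"
                 for s, a, b, c in self.stages]
        return "\n".join(lines)

    def to_rows(self) -> List[Dict]:
        return [
            {"stage": s, "n_in": a, "n_out": b, "n_removed": c}
            for s, a, b, c in self.stages
        ]


@dataclass
class CurationConfig:
    threshold_nM: float = DEFAULT_THRESHOLD_NM
    max_atoms: int = 120
    lipinski_mode: str = "strict"      # "strict": zero violations; "classic": <=1
    heavy_atoms_only: bool = False     # atom-count convention


def assign_label(activity_nM: float, threshold_nM: float = DEFAULT_THRESHOLD_NM) -> int:
    """1 iff activity is strictly below the threshold; the boundary is inactive."""
    if activity_nM <= 0:
        raise ValueError(f"activity must be positive, got {activity_nM}")
    return int(activity_nM < threshold_nM)


def deduplicate(records: Sequence[MoleculeRecord],
                threshold_nM: float = DEFAULT_THRESHOLD_NM) -> List[MoleculeRecord]:
    """Collapse records sharing a canonical SMILES to one record each.

    Multiple assay activities for the same structure collapse to their median
    and the label is recomputed from the collapsed activity. Output order
    follows first appearance of each structure.
    """
    groups: Dict[str, List[MoleculeRecord]] = {}
    order: List[str] = []
    for rec in records:
        key = rec.mol.smiles_canonical
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)

    out: List[MoleculeRecord] = []
    for key in order:
        group = groups[key]
        first = group[0]
        activities = [r.activity_nM for r in group if r.activity_nM is not None]
        if activities:
            activity = float(statistics.median(activities))
            label = assign_label(activity, threshold_nM)
            source = "assay" if any(r.source == "assay" for r in group) else first.source
        else:
            activity, label, source = None, 0, first.source
        out.append(replace(first, activity_nM=activity, label=label, source=source))
    return out


def passes_druglikeness(desc: DescriptorSet, n_atoms: int, *,
                        max_atoms: int = 120, mode: str = "strict") -> bool:
    """Atom-count cap plus Lipinski's rule of five; boundary values pass.

    ``strict`` requires zero Lipinski violations; ``classic`` allows one.
    """
    if n_atoms > max_atoms:
        return False
    violations = sum((
        desc.mw > 500.0,
        desc.alogp > 5.0,
        desc.nhbdon > 5,
        desc.nhbacc > 10,
    ))
    if mode == "strict":
        return violations == 0
    if mode == "classic":
        return violations <= 1
    raise ValueError(f"unknown Lipinski mode {mode!r}")


def curate(raw: Sequence[RawRecord],
           config: CurationConfig = CurationConfig(),
           ) -> Tuple[List[MoleculeRecord], CurationLog]:
    """Run the full funnel: parse -> deduplicate -> label -> drug-likeness.

    Decoy rows (``source == "decoy"``) need no activity, are always labeled 0,
    and pass through the same drug-likeness filter as assay rows.
    """
    if not raw:
        raise CurationError("empty input library", CurationLog())
    log = CurationLog()

    # stage 1: parse / canonicalize
    parsed: List[MoleculeRecord] = []
    for row in raw:
        try:
            mol = parse_molecule(row.smiles, row.id,
                                 heavy_atoms_only=config.heavy_atoms_only)
        except MoleculeParseError as exc:
            logger.warning("dropping unparseable record: %s", exc)
            continue
        if row.source == "assay":
            if row.activity_nM is None:
                logger.warning("dropping assay record %s without activity", row.id)
                continue
            label = assign_label(row.activity_nM, config.threshold_nM)
        else:
            label = 0
        parsed.append(MoleculeRecord(mol=mol, activity_nM=row.activity_nM,
                                     label=label, source=row.source))
    log.add("parse", len(raw), len(parsed))

    # stage 2: deduplicate by canonical structure
    deduped = deduplicate(parsed, config.threshold_nM)
    log.add("deduplicate", len(parsed), len(deduped))

    # stage 3: (re-)label against the activity threshold — removes nothing but
    # is logged so the funnel mirrors the workflow's stage order
    for rec in deduped:
        if rec.source == "assay":
            rec.label = assign_label(rec.activity_nM, config.threshold_nM)
    log.add("label", len(deduped), len(deduped))

    # stage 4: atom-count + Lipinski filter
    survivors = [
        rec for rec in deduped
        if passes_druglikeness(compute_descriptors(rec.mol), rec.mol.n_atoms,
                               max_atoms=config.max_atoms, mode=config.lipinski_mode)
    ]
    log.add("druglikeness", len(deduped), len(survivors))

    if not survivors:
        raise CurationError("no molecules survived curation", log)
    return survivors, log


def compare_descriptors(pos: Iterable[MoleculeRecord],
                        neg: Iterable[MoleculeRecord]) -> Dict[str, float]:
    """Welch two-sample t-test p-values per descriptor, positives vs negatives.

    Returns ``{descriptor: p_value}`` for MW, apol, ALogP, nHBDon, nRot and
    nHBAcc. Degenerate comparisons (both groups constant and identical) give
    p = 1.0 with a warning.
    """
    pos_desc = [compute_descriptors(r.mol) for r in pos]
    neg_desc = [compute_descriptors(r.mol) for r in neg]
    if len(pos_desc) < 2 or len(neg_desc) < 2:
        raise ValueError("need at least two molecules per group")

    pvalues: Dict[str, float] = {}
    for name in COMPARED_DESCRIPTORS:
        a = np.array([getattr(d, name) for d in pos_desc], dtype=float)
        b = np.array([getattr(d, name) for d in neg_desc], dtype=float)
        if a.std() == 0.0 and b.std() == 0.0 and a.mean() == b.mean():
            warnings.warn(f"descriptor {name}: both groups constant and equal; p=1")
            pvalues[name] = 1.0
            continue
        with np.errstate(invalid="ignore"):
            result = stats.ttest_ind(a, b, equal_var=False)
        p = float(result.pvalue)
        pvalues[name] = 1.0 if np.isnan(p) else p
    return pvalues
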