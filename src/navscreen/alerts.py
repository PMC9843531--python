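"""Privileged-substructure (structural-alert) mining and related analyses.

Circular atom environments (radii 2, 3 and 4 bonds, the neighborhoods that
ECFP4-style fingerprints hash) are enumerated over a labeled library and each
distinct environment is tested for enrichment among actives with a one-sided
upper-tail binomial test against the library-wide active fraction. Fragments
that are significantly over-represented among actives are reported as alerts.

Also here: the sulfonamide ("sulfa drug") partition of the positive class and
the per-fingerprint-family PCA separation analysis with a silhouette score as
the quantitative stand-in for visual cluster separation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .chem import fingerprint_matrix, matches_smarts
from .curation import MoleculeRecord

logger = logging.getLogger(__name__)

#: canonical sulfonamide core: sulfur doubly bonded to two oxygens, bonded to N
SULFONAMIDE_SMARTS = "S(=O)(=O)N"

DEFAULT_RADII = (2, 3, 4)
DEFAULT_MIN_COUNT = 5


@dataclass(frozen=True)
class SubstructureOccurrence:
    key: str        # canonical fragment SMILES of the atom environment
    radius: int
    n_total: int    # compounds containing the environment
    n_active: int   # active compounds containing it

    def __post_init__(self) -> None:
        if not 0 <= self.n_active <= self.n_total:
            raise ValueError("need 0 <= n_active <= n_total")


@dataclass(frozen=True)
class AlertSubstructure:
    occurrence: SubstructureOccurrence
    p_value: float
    significant: bool

    @property
    def key(self) -> str:
        return self.occurrence.key


def _environment_keys(mol: Chem.Mol, radii: Sequence[int]) -> Set[Tuple[int, str]]:
    """Distinct (radius, canonical fragment) pairs present in one molecule."""
    keys: Set[Tuple[int, str]] = set()
    for radius in radii:
        for atom in range(mol.GetNumAtoms()):
            bond_path = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, atom)
            if not bond_path:
                continue
            submol = Chem.PathToSubmol(mol, bond_path)
            if submol.GetNumAtoms() == 0:
                continue
            keys.add((radius, Chem.MolToSmiles(submol)))
    return keys


def enumerate_environments(records: Sequence[MoleculeRecord],
                           radii: Sequence[int] = DEFAULT_RADII,
                           ) -> List[SubstructureOccurrence]:
    """Tally circular environments at compound level (presence/absence).

    A molecule embedding the same environment several times still contributes
    exactly one count, so ``n_total`` never exceeds the library size.
    """
    totals: Dict[Tuple[int, str], int] = {}
    actives: Dict[Tuple[int, str], int] = {}
    for rec in records:
        for key in _environment_keys(rec.mol.rdmol(), radii):
            totals[key] = totals.get(key, 0) + 1
            if rec.label == 1:
                actives[key] = actives.get(key, 0) + 1
    return [
        SubstructureOccurrence(key=smiles, radius=radius,
                               n_total=totals[(radius, smiles)],
                               n_active=actives.get((radius, smiles), 0))
        for radius, smiles in sorted(totals)
    ]


def alert_pvalue(n_total: int, n_active: int, background_rate: float) -> float:
    """One-sided upper-tail binomial p-value for active enrichment.

    p = P[X >= n_active] with X ~ Binomial(n_total, background_rate), i.e. the
    probability of seeing at least this many actives among the compounds
    carrying the fragment if the fragment were unrelated to activity.
    """
    if not 0.0 < background_rate < 1.0:
        raise ValueError(f"background rate must lie in (0, 1), got {background_rate}")
    if not 0 <= n_active <= n_total:
        raise ValueError("need 0 <= n_active <= n_total")
    return float(stats.binom.sf(n_active - 1, n_total, background_rate))


def extract_alerts(records: Sequence[MoleculeRecord],
                   radii: Sequence[int] = DEFAULT_RADII,
                   alpha: float = 0.05,
                   min_count: int = DEFAULT_MIN_COUNT,
                   correction: str | None = None,
                   ) -> List[AlertSubstructure]:
    """Mine alerts: enumerate, test, keep significant, sort by p ascending.

    ``correction=None`` applies the raw p < alpha rule; ``correction="bh"``
    switches to Benjamini-Hochberg adjusted p-values. Ties in p are broken by
    larger n_active, then by fragment key. An empty result is not an error.
    """
    labels = {r.label for r in records}
    if labels != {0, 1}:
        raise ValueError("alert mining needs both classes present")
    n_actives = sum(r.label for r in records)
    background = n_actives / len(records)

    occurrences = enumerate_environments(records, radii)
    pvalues = np.array([alert_pvalue(o.n_total, o.n_active, background)
                        for o in occurrences])
    if correction == "bh" and len(pvalues):
        _, pvalues, _, _ = multipletests(pvalues, alpha=alpha, method="fdr_bh")
    elif correction not in (None, "bh"):
        raise ValueError(f"unknown correction {correction!r}")

    alerts = [
        AlertSubstructure(occurrence=occ, p_value=float(p),
                          significant=bool(p < alpha and occ.n_total >= min_count))
        for occ, p in zip(occurrences, pvalues)
    ]
    significant = [a for a in alerts if a.significant]
    significant.sort(key=lambda a: (a.p_value, -a.occurrence.n_active, a.key))
    if not significant:
        logger.info("no significant alerts at alpha=%g (tested %d environments)",
                    alpha, len(alerts))
    return significant


def alerts_table(alerts: Sequence[AlertSubstructure]) -> pd.DataFrame:
    return pd.DataFrame([
        {"environment": a.occurrence.key, "radius": a.occurrence.radius,
         "n_total": a.occurrence.n_total, "n_active": a.occurrence.n_active,
         "p_value": a.p_value, "significant": a.significant}
        for a in alerts
    ])


def sulfa_partition(positives: Sequence[MoleculeRecord],
                    pattern: str = SULFONAMIDE_SMARTS,
                    ) -> Tuple[List[str], List[str]]:
    """Split positives into sulfonamide-containing and the rest (by SMARTS)."""
    sulfa, non_sulfa = [], []
    for rec in positives:
        (sulfa if matches_smarts(rec.mol, pattern) else non_sulfa).append(rec.mol.id)
    return sulfa, non_sulfa


def pca_separation(records: Sequence[MoleculeRecord],
                   groups: Sequence[int],
                   family: str) -> Dict:
    """Project one fingerprint family onto its first two PCs; score separation.

    Returns the 2-D coordinates, the explained-variance ratios, and the
    silhouette coefficient of the two groups in PC space. Groups must each
    contain at least three molecules.
    """
    groups = np.asarray(groups, dtype=int)
    if len(records) != len(groups):
        raise ValueError("records/groups length mismatch")
    values, counts = np.unique(groups, return_counts=True)
    if len(values) != 2 or counts.min() < 3:
        raise ValueError("need exactly two groups with >= 3 molecules each")

    X = fingerprint_matrix([r.mol for r in records], family).astype(float)
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError(f"{family}: all fingerprint bits constant; PCA degenerate")
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X)
    return {
        "family": family,
        "coordinates": coords,
        "explained_variance_ratio": pca.explained_variance_ratio_.tolist(),
        "silhouette": float(silhouette_score(coords, groups)),
    }
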