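"""Redundancy reduction and data splitting.

Bioactivity libraries are full of near-duplicate analogs reported together, so
a random split leaks structural information between train and test. This
module clusters compounds by ECFP4 Tanimoto distance with average linkage,
keeps one medoid per cluster (undersampling), scans the cluster cutoff, and
performs the stratified train/validation/test split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .chem import Fingerprint, compute_descriptors, compute_fingerprint, tanimoto
from .curation import MoleculeRecord

#: fingerprint family fixed for similarity, clustering and heatmaps
SIMILARITY_FAMILY = "ecfp4"


@dataclass
class SimilarityMatrix:
    ids: List[str]
    values: np.ndarray  # symmetric, unit diagonal, entries in [0, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class ClusterAssignment:
    cutoff: float
    cluster_of: Dict[str, int]          # molecule id -> cluster id
    representative_of: Dict[int, str]   # cluster id -> medoid molecule id

    @property
    def n_clusters(self) -> int:
        return len(self.representative_of)


@dataclass
class DataSplit:
    train: List[str]
    validation: List[str]
    test: List[str]
    class_counts: Dict[str, Dict[int, int]]

    def all_ids(self) -> List[str]:
        return self.train + self.validation + self.test

    def __post_init__(self) -> None:
        sets = [set(self.train), set(self.validation), set(self.test)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("train/validation/test id sets overlap")


def _ecfp4_fingerprints(records: Sequence[MoleculeRecord]) -> List[Fingerprint]:
    return [compute_fingerprint(r.mol, SIMILARITY_FAMILY) for r in records]


def similarity_stats(fps: Sequence[Fingerprint],
                     ids: Sequence[str] | None = None,
                     ) -> Tuple[SimilarityMatrix, float]:
    """Full pairwise Tanimoto matrix and the mean over the upper triangle."""
    n = len(fps)
    if n < 2:
        raise ValueError("need at least two fingerprints")
    ids = list(ids) if ids is not None else [str(i) for i in range(n)]
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = tanimoto(fps[i], fps[j])
    mean = float(values[np.triu_indices(n, k=1)].mean())
    return SimilarityMatrix(ids=ids, values=values), mean


def _medoid(ids: List[str], sim: np.ndarray, members: List[int]) -> str:
    """Cluster member with maximal mean similarity to the rest; ties -> min id."""
    if len(members) == 1:
        return ids[members[0]]
    sub = sim[np.ix_(members, members)]
    mean_sim = (sub.sum(axis=1) - 1.0) / (len(members) - 1)
    best = max(zip(mean_sim, (ids[m] for m in members)),
               key=lambda t: (t[0], _NegStr(t[1])))
    return best[1]


class _NegStr(str):
    """Inverts string comparison so max() breaks ties toward the smallest id."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def cluster_undersample(records: Sequence[MoleculeRecord], cutoff: float,
                        method: str = "average",
                        ) -> Tuple[ClusterAssignment, List[MoleculeRecord]]:
    """Average-linkage clustering on 1 - Tanimoto(ECFP4), cut at ``cutoff``.

    Each cluster keeps exactly one representative: its medoid (maximal mean
    intra-cluster similarity, ties broken toward the lexicographically
    smallest id). Retained records preserve input order.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in [0, 1], got {cutoff}")
    ids = [r.mol.id for r in records]
    if len(records) == 1:
        assign = ClusterAssignment(cutoff, {ids[0]: 1}, {1: ids[0]})
        return assign, list(records)

    fps = _ecfp4_fingerprints(records)
    sim_matrix, _ = similarity_stats(fps, ids)
    dist = 1.0 - sim_matrix.values
    np.fill_diagonal(dist, 0.0)
    tree = linkage(squareform(dist, checks=False), method=method)
    labels = fcluster(tree, t=cutoff, criterion="distance")

    cluster_of = dict(zip(ids, (int(c) for c in labels)))
    representative_of: Dict[int, str] = {}
    for cluster in sorted(set(cluster_of.values())):
        members = [i for i, mid in enumerate(ids) if cluster_of[mid] == cluster]
        representative_of[cluster] = _medoid(ids, sim_matrix.values, members)

    keep = set(representative_of.values())
    retained = [r for r in records if r.mol.id in keep]
    return ClusterAssignment(cutoff, cluster_of, representative_of), retained


def cutoff_scan(records: Sequence[MoleculeRecord],
                cutoffs: Sequence[float]) -> pd.DataFrame:
    """Retained-representative counts over an ascending grid of cutoffs."""
    if list(cutoffs) != sorted(cutoffs):
        raise ValueError("cutoffs must be sorted ascending")
    rows = []
    for cutoff in cutoffs:
        assignment, retained = cluster_undersample(records, cutoff)
        rows.append({"cutoff": cutoff, "n_retained": len(retained)})
    return pd.DataFrame(rows)


def _largest_remainder(n: int, proportions: Sequence[float]) -> List[int]:
    """Integer allocation of n over proportions by largest remainder.

    Remainder ties go to the earlier split (train before validation before
    test) so the allocation is total and deterministic.
    """
    total = float(sum(proportions))
    quotas = [n * p / total for p in proportions]
    counts = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(range(len(quotas)),
                   key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def stratified_split(records: Sequence[MoleculeRecord],
                     proportions: Sequence[float] = (2, 1, 1),
                     seed: int = 0) -> DataSplit:
    """Per-class 2:1:1 (by default) split with largest-remainder allocation.

    Ids are sorted before shuffling so the split depends only on
    (id set, proportions, seed), not on input order.
    """
    if len(proportions) != 3 or any(p < 0 for p in proportions):
        raise ValueError("proportions must be three non-negative numbers")
    if min(proportions) <= 0:
        raise ValueError("every split must receive a positive proportion")

    by_class: Dict[int, List[str]] = {}
    for rec in records:
        by_class.setdefault(rec.label, []).append(rec.mol.id)
    if set(by_class) != {0, 1}:
        raise ValueError("both classes must be present to stratify")

    rng = np.random.default_rng(seed)
    parts: Dict[str, List[str]] = {"train": [], "validation": [], "test": []}
    class_counts: Dict[str, Dict[int, int]] = {k: {0: 0, 1: 0} for k in parts}
    for label in sorted(by_class):
        ids = sorted(by_class[label])
        if len(ids) < 3:
            raise ValueError(f"class {label} has fewer molecules than splits")
        rng.shuffle(ids)
        n_train, n_val, n_test = _largest_remainder(len(ids), proportions)
        chunks = {
            "train": ids[:n_train],
            "validation": ids[n_train:n_train + n_val],
            "test": ids[n_train + n_val:],
        }
        for name, chunk in chunks.items():
            parts[name].extend(chunk)
            class_counts[name][label] = len(chunk)
    return DataSplit(train=sorted(parts["train"]),
                     validation=sorted(parts["validation"]),
                     test=sorted(parts["test"]),
                     class_counts=class_counts)


def diversity_summary(split: DataSplit,
                      records: Sequence[MoleculeRecord]) -> pd.DataFrame:
    """Long-format (split, id, mw, alogp, tpsa) table for diversity scatter."""
    membership: Dict[str, str] = {}
    for name in ("train", "validation", "test"):
        for mol_id in getattr(split, name):
            membership[mol_id] = name
    rows = []
    for rec in records:
        if rec.mol.id not in membership:
            continue
        desc = compute_descriptors(rec.mol)
        rows.append({"split": membership[rec.mol.id], "id": rec.mol.id,
                     "mw": desc.mw, "alogp": desc.alogp, "tpsa": desc.tpsa})
    return pd.DataFrame(rows)
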