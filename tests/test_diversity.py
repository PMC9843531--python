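"""Clustering undersampling, cutoff scan, similarity stats, stratified split."""

from itertools import combinations
from types import SimpleNamespace

import numpy as np
import pytest

from navscreen.chem import Fingerprint, compute_fingerprint, parse_molecule, tanimoto
from navscreen.curation import MoleculeRecord
from navscreen.diversity import (
    cluster_undersample,
    cutoff_scan,
    diversity_summary,
    similarity_stats,
    stratified_split,
    _largest_remainder,
)


def _records(smiles_list, label=1, prefix="m"):
    return [MoleculeRecord(mol=parse_molecule(s, f"{prefix}{i:03d}"),
                           activity_nM=100.0, label=label)
            for i, s in enumerate(smiles_list)]


def _random_fps(rng, n, n_on=25, n_bits=512):
    return [Fingerprint("ecfp4", 2048,
                        frozenset(rng.choice(n_bits, size=n_on, replace=False)))
            for _ in range(n)]


def brute_force_upgma(dist, cutoff):
    """O(n^3) unweighted average-linkage: merge while min average distance
    (arithmetic mean over all original cross pairs) is <= cutoff."""
    clusters = [[i] for i in range(len(dist))]
    while len(clusters) > 1:
        best, best_pair = None, None
        for a, b in combinations(range(len(clusters)), 2):
            d = np.mean([dist[i][j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best:
                best, best_pair = d, (a, b)
        if best > cutoff:
            break
        a, b = best_pair
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return {frozenset(c) for c in clusters}


class TestSimilarityStats:
    def test_identical_molecules_mean_one(self):
        fps = [compute_fingerprint(parse_molecule("CCO"), "ecfp4")] * 4
        _, mean = similarity_stats(fps)
        assert mean == 1.0

    def test_disjoint_fingerprints_mean_zero(self):
        fps = [Fingerprint("ecfp4", 2048, frozenset({i * 10, i * 10 + 1}))
               for i in range(5)]
        _, mean = similarity_stats(fps)
        assert mean == 0.0

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(3)
        fps = _random_fps(rng, 50)
        matrix, mean = similarity_stats(fps)
        sims = [tanimoto(a, b) for a, b in combinations(fps, 2)]
        assert mean == pytest.approx(np.mean(sims))
        assert np.allclose(matrix.values, matrix.values.T)
        assert np.allclose(np.diag(matrix.values), 1.0)

    def test_single_fingerprint_rejected(self):
        with pytest.raises(ValueError):
            similarity_stats([Fingerprint("ecfp4", 2048, frozenset({1}))])


class TestClusterUndersample:
    def test_identical_molecules_collapse_to_one(self):
        records = _records(["CCO", "CCO", "CCO"])
        assignment, retained = cluster_undersample(records, cutoff=0.4)
        assert assignment.n_clusters == 1
        assert len(retained) == 1

    def test_distant_molecules_all_retained(self):
        records = _records(["CCO", "c1ccc2ccccc2c1", "NS(=O)(=O)c1ccccc1",
                            "CC(C)(C)C(=O)NCCN"])
        assignment, retained = cluster_undersample(records, cutoff=0.1)
        assert len(retained) == len(records)

    def test_two_analog_families_give_two_representatives(self):
        family_a = ["CCOc1ccc2c(c1)CCN(C(=O)c1ccccc1)C2",
                    "CCCOc1ccc2c(c1)CCN(C(=O)c1ccccc1)C2",
                    "OCCOc1ccc2c(c1)CCN(C(=O)c1ccccc1)C2"]
        family_b = ["CC(C)NCC(O)COc1cccc2ccccc12",
                    "CCCNCC(O)COc1cccc2ccccc12",
                    "CCNCC(O)COc1cccc2ccccc12"]
        records = _records(family_a + family_b)
        _, retained = cluster_undersample(records, cutoff=0.4)
        assert len(retained) == 2
        kept_ids = {r.mol.id for r in retained}
        assert len(kept_ids & {"m000", "m001", "m002"}) == 1
        assert len(kept_ids & {"m003", "m004", "m005"}) == 1

    def test_representative_is_a_cluster_member(self):
        records = _records(["CCO", "CCCO", "CCCCO", "c1ccccc1"])
        assignment, _ = cluster_undersample(records, cutoff=0.6)
        for cluster, rep in assignment.representative_of.items():
            members = [m for m, c in assignment.cluster_of.items() if c == cluster]
            assert rep in members

    def test_partitions_match_brute_force_oracle(self, default_library):
        """scipy average-linkage cut equals the O(n^3) UPGMA oracle, n <= 12."""
        rng = np.random.default_rng(0)
        pool = [r for r in default_library if r.label == 1]
        for trial in range(4):
            subset = [pool[i] for i in rng.choice(len(pool), 12, replace=False)]
            from navscreen.diversity import _ecfp4_fingerprints
            fps = _ecfp4_fingerprints(subset)
            dist = 1.0 - similarity_stats(fps)[0].values
            for cutoff in (0.1, 0.3, 0.5, 0.7):
                expected = brute_force_upgma(dist, cutoff)
                assignment, _ = cluster_undersample(subset, cutoff)
                ids = [r.mol.id for r in subset]
                got = {}
                for idx, mid in enumerate(ids):
                    got.setdefault(assignment.cluster_of[mid], set()).add(idx)
                assert {frozenset(v) for v in got.values()} == expected


class TestCutoffScan:
    def test_monotone_non_increasing(self, default_library):
        positives = [r for r in default_library if r.label == 1][:80]
        scan = cutoff_scan(positives, [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
        counts = scan["n_retained"].tolist()
        assert counts == sorted(counts, reverse=True)

    def test_zero_cutoff_keeps_fingerprint_distinct_molecules(self):
        records = _records(["CCO", "CCO", "CCC", "CCN"])
        scan = cutoff_scan(records, [0.0])
        assert scan["n_retained"].iloc[0] == 3

    def test_unsorted_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            cutoff_scan(_records(["CCO", "CCC"]), [0.5, 0.1])


def _dummy_records(n_pos, n_neg):
    recs = []
    for i in range(n_pos):
        recs.append(SimpleNamespace(mol=SimpleNamespace(id=f"p{i:04d}"), label=1))
    for i in range(n_neg):
        recs.append(SimpleNamespace(mol=SimpleNamespace(id=f"n{i:04d}"), label=0))
    return recs


class TestStratifiedSplit:
    def test_largest_remainder_allocations(self):
        assert _largest_remainder(400, (2, 1, 1)) == [200, 100, 100]
        assert _largest_remainder(364, (2, 1, 1)) == [182, 91, 91]

    def test_table_sized_split(self):
        split = stratified_split(_dummy_records(364, 400), (2, 1, 1), seed=0)
        assert split.class_counts["train"] == {0: 200, 1: 182}
        assert split.class_counts["validation"] == {0: 100, 1: 91}
        assert split.class_counts["test"] == {0: 100, 1: 91}

    def test_deterministic_and_input_order_independent(self):
        recs = _dummy_records(37, 55)
        a = stratified_split(recs, (2, 1, 1), seed=5)
        b = stratified_split(list(reversed(recs)), (2, 1, 1), seed=5)
        assert a.train == b.train and a.test == b.test

    def test_partition_is_exhaustive_and_disjoint(self):
        recs = _dummy_records(23, 31)
        split = stratified_split(recs, (2, 1, 1), seed=1)
        all_ids = split.all_ids()
        assert len(all_ids) == len(set(all_ids)) == 54

    def test_zero_proportion_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(_dummy_records(10, 10), (1, 0, 1), seed=0)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(_dummy_records(2, 50), (2, 1, 1), seed=0)


class TestDiversitySummary:
    def test_rows_cover_all_molecules(self):
        records = _records(["CCO", "CCC", "CCN", "CCCC", "CCCN", "c1ccccc1",
                            "CCS", "CCCl"], label=1, prefix="p")
        records += _records(["c1ccncc1", "CC(=O)O", "CCOC", "CCCO", "OCCO",
                             "CCBr"], label=0, prefix="n")
        split = stratified_split(records, (2, 1, 1), seed=2)
        table = diversity_summary(split, records)
        assert set(table["id"]) == {r.mol.id for r in records}
        assert set(table["split"]) == {"train", "validation", "test"}
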