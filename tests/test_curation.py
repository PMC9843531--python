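"""Curation funnel: labeling, deduplication, drug-likeness, group comparison."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as scipy_stats

from navscreen.chem import DescriptorSet, compute_descriptors, parse_molecule
from navscreen.curation import (
    CurationConfig,
    CurationError,
    MoleculeRecord,
    RawRecord,
    assign_label,
    compare_descriptors,
    curate,
    deduplicate,
    passes_druglikeness,
)


def _desc(**overrides):
    base = dict(mw=350.0, apol=40.0, alogp=2.0, nhbdon=2, nhbacc=4,
                nrot=4, tpsa=60.0)
    base.update(overrides)
    return DescriptorSet(**base)


class TestLabeling:
    @pytest.mark.parametrize("activity,expected", [
        (29_999.0, 1), (30_000.0, 0), (10.0, 1), (1e6, 0),
    ])
    def test_strict_threshold(self, activity, expected):
        assert assign_label(activity) == expected

    def test_non_positive_activity_rejected(self):
        with pytest.raises(ValueError):
            assign_label(0.0)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.floats(1e-3, 1e9), st.floats(1.0, 1e6), st.floats(0.1, 1.0))
    def test_lowering_threshold_never_creates_actives(self, activity, thr, shrink):
        """Label assignment is monotone in the threshold."""
        lower = thr * shrink
        assert assign_label(activity, lower) <= assign_label(activity, thr)


class TestDeduplication:
    def test_identical_duplicates_collapse(self):
        rec = lambda i, act: MoleculeRecord(
            mol=parse_molecule("CCO", f"m{i}"), activity_nM=act, label=1)
        out = deduplicate([rec(1, 100.0), rec(2, 100.0)])
        assert len(out) == 1
        assert out[0].activity_nM == 100.0

    def test_median_activity_then_threshold(self):
        recs = [MoleculeRecord(mol=parse_molecule("CCO", f"m{i}"),
                               activity_nM=a, label=assign_label(a))
                for i, a in enumerate([1_000.0, 2_000.0, 50_000.0])]
        out = deduplicate(recs)
        assert len(out) == 1
        assert out[0].activity_nM == 2_000.0
        assert out[0].label == 1

    def test_distinct_structures_untouched(self):
        recs = [MoleculeRecord(mol=parse_molecule(s, s), activity_nM=10.0, label=1)
                for s in ("CCO", "CCC", "CCN")]
        assert deduplicate(recs) == recs


class TestDruglikeness:
    def test_boundaries_are_inclusive(self):
        assert passes_druglikeness(_desc(mw=500.0), n_atoms=50)
        assert passes_druglikeness(_desc(alogp=5.0, nhbdon=5, nhbacc=10),
                                   n_atoms=120)

    def test_atom_count_over_120_fails(self):
        assert not passes_druglikeness(_desc(), n_atoms=121)
        assert passes_druglikeness(_desc(), n_atoms=120)

    def test_single_violation_fails_strict_but_passes_classic(self):
        heavy = _desc(mw=600.0)
        assert not passes_druglikeness(heavy, n_atoms=50, mode="strict")
        assert passes_druglikeness(heavy, n_atoms=50, mode="classic")
        two = _desc(mw=600.0, alogp=6.0)
        assert not passes_druglikeness(two, n_atoms=50, mode="classic")


class TestCurate:
    def test_empty_input_is_a_pipeline_error(self):
        with pytest.raises(CurationError):
            curate([])

    def test_decoys_enter_labeled_zero(self):
        raw = [
            RawRecord("a1", "NS(=O)(=O)c1ccccc1", 500.0, "assay"),
            RawRecord("d1", "c1ccc2ccccc2c1", None, "decoy"),
            RawRecord("d2", "CCCCCO", None, "decoy"),
        ]
        out, log = curate(raw)
        decoys = [r for r in out if r.source == "decoy"]
        assert len(decoys) == 2
        assert all(r.label == 0 for r in decoys)

    def test_order_stability_of_survivor_set(self):
        smiles = ["CCO", "CCC", "CCN", "CCCC", "c1ccccc1O",
                  "CC(=O)O", "CCS", "c1ccncc1"]
        raw = [RawRecord(f"m{i}", s, 1000.0 * (i + 1), "assay")
               for i, s in enumerate(smiles)]
        survivors, _ = curate(list(raw))
        shuffled = list(raw)
        random.Random(7).shuffle(shuffled)
        survivors_shuffled, _ = curate(shuffled)
        assert ({r.mol.id for r in survivors}
                == {r.mol.id for r in survivors_shuffled})

    def test_log_counts_telescope(self):
        raw = [RawRecord(f"m{i}", s, 1000.0, "assay")
               for i, s in enumerate(["CCO", "CCO", "CCC", "bad_smiles"])]
        out, log = curate(raw)
        for _, n_in, n_out, n_removed in log.stages:
            assert n_out == n_in - n_removed
        total_removed = sum(s[3] for s in log.stages)
        assert total_removed == len(raw) - len(out)


class TestCompareDescriptors:
    def test_identical_groups_give_p_one(self):
        group = [MoleculeRecord(mol=parse_molecule(s, s), activity_nM=10.0,
                                label=1)
                 for s in ("CCO", "CCC", "CCCC", "CCN")]
        pvals = compare_descriptors(group, group)
        assert all(p == pytest.approx(1.0) for p in pvals.values())

    def test_matches_textbook_welch_formula(self):
        """Module p-values equal a hand-written Welch t computation."""
        small = [MoleculeRecord(mol=parse_molecule(s, s), activity_nM=10.0, label=1)
                 for s in ("CCO", "CCC", "CCN", "CO", "CC")]
        large = [MoleculeRecord(mol=parse_molecule(s, s), activity_nM=1e5, label=0)
                 for s in ("c1ccc2ccccc2c1", "CCCCCCCCCC", "c1ccc(-c2ccccc2)cc1",
                           "CCCCCCCCCCCC", "OCCCCCCCCCO")]
        pvals = compare_descriptors(small, large)

        def welch(a, b):
            a, b = np.asarray(a, float), np.asarray(b, float)
            va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
            t = (a.mean() - b.mean()) / math.sqrt(va + vb)
            df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
            return 2 * scipy_stats.t.sf(abs(t), df)

        for name in ("mw", "apol", "nrot"):
            a = [getattr(compute_descriptors(r.mol), name) for r in small]
            b = [getattr(compute_descriptors(r.mol), name) for r in large]
            assert pvals[name] == pytest.approx(welch(a, b), rel=1e-9)
        assert pvals["mw"] < 1e-3

    def test_tiny_groups_rejected(self):
        one = [MoleculeRecord(mol=parse_molecule("CCO", "x"),
                              activity_nM=1.0, label=1)]
        with pytest.raises(ValueError):
            compare_descriptors(one, one)
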