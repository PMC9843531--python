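# Methods

`navscreen` implements a fingerprint/machine-learning virtual-screening
workflow for binary inhibitor classification against the cardiac sodium
channel NaV1.5, together with a synthetic-library generator that reproduces
the statistical structure of real channel-pharmacology data so that every
stage can be validated against known ground truth.

## The screening problem and the pipeline

Bioactivity records for an ion-channel target arrive as (molecule, IC50)
pairs. The workflow turns them into a classifier and an interpretable
fragment analysis in five steps.

**1. Curation funnel.** Structures are parsed and canonicalized (RDKit
canonical SMILES is the identity of a compound). Records sharing a canonical
structure collapse to one record carrying the *median* of their assay values
— robust to outlier assays and deterministic — and the label is recomputed
from the collapsed value. Labels are assigned by a strict threshold: active
(label 1) iff IC50 < 30,000 nM; the boundary value is inactive. Compounds
with more than 120 atoms (hydrogens included; a heavy-atom convention is
available via `CurationConfig.heavy_atoms_only`) are removed, then Lipinski's
rule of five is applied as a hard filter (default: zero violations; the
classic one-violation reading is a config switch; boundary values such as
MW = 500.0 pass). Decoy records enter the same drug-likeness filter and are
always labeled 0. Every stage logs (n_in, n_out, n_removed) and the funnel
telescopes.

**2. Redundancy reduction.** Inhibitor series published together are
near-duplicates; left alone they leak structural information across data
splits and inflate evaluation metrics. Positives are clustered by
agglomerative average linkage (UPGMA) on Tanimoto distance
(1 − similarity) over ECFP4 fingerprints, the tree is cut at a distance
cutoff, and each cluster keeps exactly one representative — its medoid
(maximal mean intra-cluster similarity; ties go to the lexicographically
smallest id, so the outcome is total and reproducible). The cutoff is chosen
from a retention scan over 0.1–0.8. For the synthetic libraries the default
cutoff is 0.2: the retention curve drops steeply between 0.1 and 0.2 (the
analog-family scale, intra-family distance ≈ 0.13) and 0.2 retains
approximately one representative per family, which is exactly the
redundancy being removed. Negatives are deliberately not clustered; a broad
negative chemical space is what a screening model must reject.

**3. Stratified 2:1:1 split.** Train/validation/test sizes are allocated
per class by the largest-remainder rule (ties to the earlier split), ids are
sorted before seeded shuffling, so the split depends only on (id set,
proportions, seed), never on input order. 400 negatives split 200/100/100;
364 positives split 182/91/91.

**4. Model grid.** Five algorithms (logistic regression, SVM, Bernoulli
naive Bayes, MLP, random forest; scikit-learn) × six fingerprint families
(below) = 30 models. Hyperparameters come from small exhaustive grids
(regularization over decades for LR/SVM, linear vs RBF kernel, smoothing for
NB, hidden sizes and weight decay for the MLP, tree count and depth for RF),
scored by mean 5-fold cross-validated MCC — MCC is the workflow's headline
metric throughout — with ties resolved by grid order. Binary fingerprint
bits are fed as 0/1 features without scaling. Metrics are computed from the
confusion matrix as

    Q   = (TP+TN)/(TP+TN+FP+FN)        SE = TP/(TP+FN)
    SP  = TN/(TN+FP)
    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with any zero denominator mapped to 0 (a degenerate classifier carries no
correlation). Class probabilities are thresholded at 0.5 (configurable).
ROC and precision–recall AUCs are trapezoidal. Models are ranked by
validation MCC (ties: ROC AUC, then name); the top 10 are re-scored on the
test set and the top 5 form a simple majority-vote ensemble (odd committee
required; 3-of-5 votes decide). Every `evaluate` call verifies that the
evaluation ids are disjoint from the training ids and hard-fails otherwise —
the data-leakage guard that motivates step 2.

**5. Alert mining and interpretation.** Circular atom environments —
the neighborhoods ECFP-style fingerprints hash — are enumerated at radii
2, 3 and 4 bonds around every atom, canonicalized as fragment SMILES, and
tallied at compound level (an environment embedded twice in one molecule
counts once). Each environment carried by at least `min_count = 5`
compounds is tested for enrichment among actives with a one-sided
upper-tail binomial test: with q the library-wide active fraction and the
environment present in n_total compounds of which n_active are active,

    p = Σ_{i=n_active..n_total} C(n_total, i) q^i (1−q)^{n_total−i},

computed via the stable survival function (scipy). Environments with
p < 0.05 (raw, for fidelity to common practice; Benjamini–Hochberg is a
switch) are reported sorted by p, ties broken by larger n_active then by
fragment key. Separately, positives are partitioned by the sulfonamide core
SMARTS `S(=O)(=O)N` ("sulfa drugs"), and each fingerprint family is
projected onto its first two principal components; the silhouette
coefficient of the sulfa/non-sulfa groups in PC space quantifies what a
scatter plot would show visually. The min_count default suppresses
singleton artifacts; alpha and the SMARTS pattern are configurable.

## Fingerprint families

Six families feed the model grid, with fixed lengths as a hard contract:

| family          | bits | construction                                         |
|-----------------|------|------------------------------------------------------|
| `cdk_path`      | 1024 | hashed linear paths to depth 5                       |
| `estate`        |   79 | E-state atom-type bins, binarized                    |
| `extended_path` | 1024 | hashed branched paths to depth 7                     |
| `graph_only`    | 1024 | hashed paths ignoring bond order (connectivity only) |
| `maccs`         |  166 | MACCS structural keys (RDKit's 167 minus the unused bit 0) |
| `pubchem_keys`  |  881 | hashed radius-1 circular environments folded to 881 bits |

ECFP4 (radius-2 Morgan hashed to 2048 bits, the community default length)
is reserved for similarity, clustering and alert mining. The four hashed
families are built on RDKit generators configured to probe genuinely
different graph views; reproducing the exact bit definitions of other
toolkits' fingerprints of the same names is explicitly not a goal — the
family abstraction and the length contracts are. For `pubchem_keys` no
installed library provides the classic 881 keyed substructure definitions,
so the family is realized as a hashed circular fingerprint at that length;
it plays the same role in the grid (a short, local-environment descriptor).

The `apol` descriptor (summed atomic polarizability, hydrogens included)
is computed from a built-in table of CRC atomic polarizabilities; the other
six descriptors (MW, ALogP, H-bond donors/acceptors, rotatable bonds, TPSA)
come from RDKit. Positives and negatives are compared per descriptor with
Welch's unequal-variance t-test (groups differ in size and spread; at the
p-values involved the choice vs pooled-variance t is immaterial).

## The synthetic data generator

`synthetic.generate_library` emulates the structure of real channel
bioactivity data:

* **Analog families.** Each family is one of 15 hand-written drug-like
  scaffolds (24–27 heavy atoms) carrying three map-numbered attachment
  points, zipped (RDKit `molzip`) with (a) a member-specific small
  substituent at the end of a linker built into the scaffold, (b) an
  aromatic site receiving either the planted fragment or a small cap, and
  (c) a family-identity substituent so families sharing a scaffold are
  distinct compounds. Because members differ only at a linker terminus,
  mean intra-family ECFP4 Tanimoto exceeds 0.85 by construction (measured
  0.867–0.870 across seeds) while inter-family similarity stays near 0.26
  — the analog-redundancy premise of the undersampling stage. Scaffold and
  substituent budgets are sized so every combination passes the
  drug-likeness filter.
* **Planted privileged fragment.** A sulfonamide (`S(N)(=O)=O` on an
  aromatic carbon) is attached to an exact quota of families per class
  (fraction `enrichment_active` of active families, `enrichment_inactive`
  of inactive ones) and per molecule for decoys. Nothing else in the
  vocabularies contains a sulfonamide, so ground truth is unambiguous.
* **Assay noise.** IC50 values are lognormal: a per-class family median
  (active median 3,000 nM, σ_ln = 1.0; inactive 150,000 nM, σ_ln = 0.8)
  times member-level jitter (σ_ln = 0.3). The distributions straddle the
  30,000 nM threshold, so threshold labels are imperfect in a controlled
  way, as in real assays.
* **Decoys.** Structurally heterogeneous smaller molecules from a separate
  24-scaffold vocabulary, always inactive, with no recorded activity —
  the "randomly extracted negatives" of a screening background.

Default study conditions: 40 active + 20 inactive families (Poisson family
size, mean 5, capped by the substituent vocabulary) + 150 decoys ≈ 450
molecules, positive:negative ≈ 1:1.2 after curation. Two derived presets:
the **classification benchmark** (78 + 39 families + 200 decoys ≈ 800
molecules, enrichment 1.0/0.0, tight IC50 spread — separable by
construction) and the **alert-mining benchmark** (≈ 400 molecules,
enrichment 0.9/0.1). The same seed reproduces a library byte-for-byte.

What the generator does **not** emulate: activity cliffs, assay-condition
heterogeneity, measured-vs-censored values, tautomer/salt ambiguity, and
chemotype diversity beyond the scaffold vocabulary (at most
15 × 8 = 120 distinct families). Passing tests on these libraries
demonstrates that the machinery is correct and calibrated — not that any
particular real-data accuracy will be reached; real ChEMBL-scale inputs
enter through the same CSV/SDF interface.

## Numerical and design choices

* Tanimoto of two all-zero fingerprints is defined as 1.0 (reflexivity),
  with a warning.
* Binomial p-values use the survival function, stable to n_total = 10^4;
  an exact rational-arithmetic oracle validates them to 1e-12 in tests.
* Average-linkage clustering uses scipy's UPGMA on the condensed distance
  matrix; a brute-force O(n³) merge oracle validates the cut partitions on
  small instances.
* SVMs skip Platt probability calibration during grid CV (hard labels
  suffice for MCC scoring) and enable it only for the final refit.
* The permutation-null check of the classification benchmark scores every
  model on the combined validation + test pool (~380 molecules): the null
  sd of MCC scales as n^(-1/2), and the combined pool is the complete
  held-out portion of the data.
* "Experimentally verified" provenance filtering cannot be reconstructed
  from a plain molecule table; an optional pass-through flag column is
  honored when present, otherwise the stage is a no-op.
* Problem sizes in tests and the acceptance script (libraries of ~400–800
  molecules, 20 alert-recovery seeds, 10 sulfa/PCA seeds) were chosen as
  the smallest designs at which the planted effects are unambiguous.

## Known limitations

* The six fingerprint families are *functional* analogs, not bit-exact
  reimplementations, of the families of the same names in other toolkits.
* Alert mining reports raw p-values by default; with thousands of
  environments tested, the significant list under the raw rule contains an
  expected α·m false positives (the BH switch addresses this).
* The medoid representative keeps the most central chemistry of a cluster;
  other choices (e.g. most potent member) are scientifically defensible and
  not implemented.
* PCA separation is judged on the first two components only, matching the
  visual analysis it replaces.
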