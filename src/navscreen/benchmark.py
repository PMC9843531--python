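"""Reference benchmarks exercised by the test suite and the acceptance script.

These wrap the library stages into the fixed study designs used to validate
the pipeline: the separable classification benchmark (planted fingerprint
signal, 2:1:1 stratified split, full model grid), its permuted-label null,
the planted-alert recovery design, and the sulfa/PCA separation comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .alerts import extract_alerts, pca_separation, sulfa_partition
from .chem import MODEL_FAMILIES, fingerprint_matrix
from .curation import CurationConfig, RawRecord, curate, MoleculeRecord
from .diversity import stratified_split
from .modeling import (EvalReport, TrainedModel, ensemble_vote,
                       confusion_from_predictions, evaluate, mcc,
                       run_model_grid, top_k)
from .synthetic import (alert_library_spec, benchmark_library_spec,
                        generate_library)


def curated_library(spec) -> List[MoleculeRecord]:
    """Generate a library and push it through the curation funnel."""
    generated = generate_library(spec)
    raw = [RawRecord(id=r.mol.id, smiles=r.mol.smiles_canonical,
                     activity_nM=r.activity_nM, source=r.source)
           for r in generated]
    curated, _ = curate(raw, CurationConfig())
    # restore generator ground-truth annotations lost through the funnel
    meta = {r.mol.id: r for r in generated}
    for rec in curated:
        origin = meta.get(rec.mol.id)
        if origin is not None:
            rec.family, rec.planted = origin.family, origin.planted
    return curated


@dataclass
class GridBenchmarkResult:
    models: Dict[str, TrainedModel]
    validation_reports: List[EvalReport]
    test_reports: List[EvalReport]
    heldout_reports: List[EvalReport]   # every model on validation + test
    best_test_mcc: float
    ensemble_test_mcc: float


def _split_features(records: Sequence[MoleculeRecord], seed: int,
                    families: Sequence[str]):
    split = stratified_split(records, (2, 1, 1), seed)
    by_id = {r.mol.id: r for r in records}
    ids = {name: list(getattr(split, name))
           for name in ("train", "validation", "test")}
    labels = {name: np.array([by_id[m].label for m in ids[name]])
              for name in ids}
    features = {
        family: {name: fingerprint_matrix([by_id[m].mol for m in ids[name]],
                                          family) for name in ids}
        for family in families
    }
    return ids, labels, features


def classification_benchmark(seed: int = 0,
                             families: Sequence[str] = MODEL_FAMILIES,
                             permute_labels: bool = False,
                             ) -> GridBenchmarkResult:
    """Full model grid on the separable planted-signal benchmark.

    With ``permute_labels`` the class labels are shuffled (same seed stream)
    before splitting, which destroys every structure-activity relationship
    and should leave all models near MCC 0 on held-out data.
    """
    records = curated_library(benchmark_library_spec(seed=seed))
    if permute_labels:
        rng = np.random.default_rng(seed + 1)
        labels = np.array([r.label for r in records])
        rng.shuffle(labels)
        for rec, label in zip(records, labels):
            rec.label = int(label)   # deliberately divorced from structure

    ids, labels, features = _split_features(records, seed, families)
    models, val_reports = run_model_grid(features, labels, ids, seed=seed,
                                         families=families)

    # every model scored on the full held-out pool (validation + test)
    heldout_ids = ids["validation"] + ids["test"]
    heldout_labels = np.concatenate([labels["validation"], labels["test"]])
    heldout_reports = []
    for model in models.values():
        family = model.spec.fingerprint
        X = np.vstack([features[family]["validation"], features[family]["test"]])
        heldout_reports.append(evaluate(model, X, heldout_labels, heldout_ids,
                                        eval_set="heldout"))

    test_reports = []
    for report in top_k(val_reports, min(10, len(val_reports))):
        model = models[report.model_name]
        family = model.spec.fingerprint
        test_reports.append(evaluate(model, features[family]["test"],
                                     labels["test"], ids["test"],
                                     eval_set="test"))
    best_test_mcc = max(r.mcc for r in test_reports)

    k = min(5, len(val_reports))
    if k % 2 == 0:
        k -= 1
    top_names = [r.model_name for r in top_k(val_reports, k)]
    votes = np.vstack([
        next(t for t in test_reports if t.model_name == name).predictions
        for name in top_names])
    cm = confusion_from_predictions(labels["test"], ensemble_vote(votes))
    return GridBenchmarkResult(models=models, validation_reports=val_reports,
                               test_reports=test_reports,
                               heldout_reports=heldout_reports,
                               best_test_mcc=best_test_mcc,
                               ensemble_test_mcc=mcc(cm))


def planted_alert_recovery(seed: int) -> Tuple[bool, float]:
    """One alert-mining run: is the top-ranked alert the planted fragment?

    Returns (recovered, top_p). Recovery means the compounds carrying the
    top-ranked environment are a subset of the planted compounds and cover
    at least half of them (the planted fragment appears in slightly varying
    attachment contexts, so a single environment need not cover every
    planted molecule).
    """
    records = curated_library(alert_library_spec(seed=seed))
    alerts = extract_alerts(records)
    if not alerts:
        return False, 1.0
    top = alerts[0]
    from .alerts import _environment_keys
    planted_ids = {r.mol.id for r in records if r.planted}
    carriers = set()
    for rec in records:
        keys = _environment_keys(rec.mol.rdmol(), (top.occurrence.radius,))
        if (top.occurrence.radius, top.occurrence.key) in keys:
            carriers.add(rec.mol.id)
    recovered = bool(planted_ids) and carriers <= planted_ids and (
        len(carriers) >= 0.5 * len(planted_ids))
    return recovered, top.p_value


def sulfa_pca_benchmark(seed: int, keyed_family: str = "maccs",
                        hashed_family: str = "graph_only") -> Dict:
    """Silhouette comparison of a keyed vs a bond-order-blind fingerprint
    on the sulfa/non-sulfa partition of the positives."""
    from .synthetic import default_library_spec

    records = curated_library(default_library_spec(seed=seed))
    positives = [r for r in records if r.label == 1]
    sulfa_ids, non_sulfa = sulfa_partition(positives)
    groups = [int(r.mol.id in set(sulfa_ids)) for r in positives]
    n_planted = sum(1 for r in positives if r.planted)
    result = {"n_sulfa": len(sulfa_ids), "n_non_sulfa": len(non_sulfa),
              "n_planted_positives": n_planted}
    for role, family in (("keyed", keyed_family), ("hashed", hashed_family)):
        result[role] = pca_separation(positives, groups, family)["silhouette"]
    return result
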