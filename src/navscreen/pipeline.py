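"""End-to-end orchestration, configuration and standard-format I/O.

The pipeline chains the analysis stages in their canonical order:

    simulate/load -> curate -> undersample (positives) -> split ->
    fingerprint -> train/evaluate grid -> rank -> ensemble -> alerts/sulfa/PCA

Every stage writes its tables under the configured output directory, and a
run manifest (config, seed, package versions, stage list) makes a run
re-executable from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem

from . import __version__
from .alerts import (alerts_table, extract_alerts, pca_separation,
                     sulfa_partition, SULFONAMIDE_SMARTS)
from .chem import MODEL_FAMILIES, fingerprint_matrix, parse_molecule
from .curation import (CurationConfig, MoleculeRecord, RawRecord, curate,
                       compare_descriptors)
from .diversity import (cluster_undersample, cutoff_scan, diversity_summary,
                        similarity_stats, stratified_split, _ecfp4_fingerprints)
from .modeling import (ensemble_vote, evaluate, rank_models, run_model_grid,
                       top_k)
from .synthetic import LibrarySpec, generate_library

logger = logging.getLogger(__name__)

STAGES = ("simulate", "curate", "undersample", "split", "fingerprint",
          "train", "rank", "ensemble", "alerts")


class ConfigError(ValueError):
    """Raised for invalid or unknown configuration keys."""


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run; unknown keys are rejected."""

    seed: int = 0
    output_dir: str = "results/pipeline"
    input_path: Optional[str] = None          # CSV/SMI/SDF; None -> synthetic
    input_format: str = "csv"
    library: Dict = field(default_factory=dict)   # LibrarySpec overrides
    curation: Dict = field(default_factory=dict)  # CurationConfig overrides
    cluster_cutoff: float = 0.2
    cutoff_grid: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
    split_proportions: Sequence[float] = (2, 1, 1)
    heatmap_subsample: int = 100
    algorithms: Optional[Sequence[str]] = None     # None -> all five
    families: Sequence[str] = MODEL_FAMILIES
    grids: Dict = field(default_factory=dict)      # per-algorithm overrides
    alert_radii: Sequence[int] = (2, 3, 4)
    alert_alpha: float = 0.05
    alert_min_count: int = 5
    sulfa_pattern: str = SULFONAMIDE_SMARTS
    save_models: bool = False      # serialize each trained model to disk

    def __post_init__(self) -> None:
        if not 0.0 <= self.cluster_cutoff <= 1.0:
            raise ConfigError(f"cluster_cutoff outside [0,1]: {self.cluster_cutoff}")
        if len(self.split_proportions) != 3 or min(self.split_proportions) <= 0:
            raise ConfigError("split_proportions must be three positive numbers")
        if not 0.0 < self.alert_alpha <= 1.0:
            raise ConfigError(f"alert_alpha outside (0,1]: {self.alert_alpha}")
        if list(self.cutoff_grid) != sorted(self.cutoff_grid):
            raise ConfigError("cutoff_grid must be ascending")

    @classmethod
    def from_dict(cls, data: Dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> Dict:
        out = dataclasses.asdict(self)
        out["cutoff_grid"] = list(self.cutoff_grid)
        out["split_proportions"] = list(self.split_proportions)
        out["alert_radii"] = list(self.alert_radii)
        out["families"] = list(self.families)
        if self.algorithms is not None:
            out["algorithms"] = list(self.algorithms)
        return out


# ---------------------------------------------------------------- I/O


def io_read_molecules(path: str | Path, fmt: str = "csv") -> List[RawRecord]:
    """Read a molecule table from CSV, SMILES (.smi) or SDF."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "csv":
        frame = pd.read_csv(path)
        required = {"molecule_id", "smiles"}
        if not required <= set(frame.columns):
            raise ConfigError(f"CSV must provide columns {sorted(required)}")
        records = []
        for _, row in frame.iterrows():
            # optional provenance flag: rows explicitly marked unverified
            # are dropped before curation
            if "verified" in frame.columns and not pd.isna(row["verified"]):
                if not bool(row["verified"]):
                    continue
            activity = row.get("ic50_nM")
            activity = None if pd.isna(activity) else float(activity)
            source = row.get("source", "assay")
            source = "assay" if pd.isna(source) else str(source)
            if source == "assay" and activity is None:
                raise ConfigError(
                    f"assay row {row['molecule_id']} lacks an ic50_nM value")
            records.append(RawRecord(id=str(row["molecule_id"]),
                                     smiles=str(row["smiles"]),
                                     activity_nM=activity, source=source))
        return records
    if fmt == "smi":
        records = []
        for line_no, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"line{line_no}"
            records.append(RawRecord(id=mol_id, smiles=smiles,
                                     activity_nM=None, source="decoy"))
        return records
    if fmt == "sdf":
        records = []
        supplier = Chem.SDMolSupplier(str(path))
        for idx, mol in enumerate(supplier):
            if mol is None:
                logger.warning("skipping unreadable SDF entry %d", idx)
                continue
            mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else f"sdf{idx}"
            activity = (float(mol.GetProp("ic50_nM"))
                        if mol.HasProp("ic50_nM") else None)
            source = mol.GetProp("source") if mol.HasProp("source") else (
                "assay" if activity is not None else "decoy")
            records.append(RawRecord(id=mol_id, smiles=Chem.MolToSmiles(mol),
                                     activity_nM=activity, source=source))
        return records
    raise ConfigError(f"unsupported input format {fmt!r}")


def records_to_frame(records: Sequence[MoleculeRecord]) -> pd.DataFrame:
    from .chem import compute_descriptors

    rows = []
    for rec in records:
        desc = compute_descriptors(rec.mol)
        rows.append({
            "molecule_id": rec.mol.id, "smiles": rec.mol.smiles_canonical,
            "ic50_nM": rec.activity_nM, "source": rec.source,
            "label": rec.label, "mw": desc.mw, "apol": desc.apol,
            "alogp": desc.alogp, "nhbdon": desc.nhbdon, "nhbacc": desc.nhbacc,
            "nrot": desc.nrot, "tpsa": desc.tpsa,
        })
    return pd.DataFrame(rows)


def io_write_molecules(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def io_write_smiles(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    """Write canonical SMILES, one molecule per line: smiles<TAB>id."""
    lines = [f"{r.mol.smiles_canonical}\t{r.mol.id}" for r in records]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------- pipeline


def _library_records(config: PipelineConfig) -> List[RawRecord]:
    if config.input_path is not None:
        return io_read_molecules(config.input_path, config.input_format)
    spec = LibrarySpec(**{"seed": config.seed, **config.library})
    generated = generate_library(spec)
    return [RawRecord(id=r.mol.id, smiles=r.mol.smiles_canonical,
                      activity_nM=r.activity_nM, source=r.source)
            for r in generated]


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute every stage; returns a result bundle of DataFrames/objects."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    completed: List[str] = []
    bundle: Dict = {}

    # 1. simulate or load
    raw = _library_records(config)
    completed.append("simulate")

    # 2. curate
    curated, log = curate(raw, CurationConfig(**config.curation))
    pd.DataFrame(log.to_rows()).to_csv(out / "curation_log.csv", index=False)
    io_write_molecules(curated, out / "curated.csv")
    positives = [r for r in curated if r.label == 1]
    negatives = [r for r in curated if r.label == 0]
    bundle["curated"], bundle["curation_log"] = curated, log
    if len(positives) >= 2 and len(negatives) >= 2:
        pvals = compare_descriptors(positives, negatives)
        pd.DataFrame([pvals]).to_csv(out / "descriptor_ttest.csv", index=False)
        bundle["descriptor_pvalues"] = pvals
    completed.append("curate")

    # 3. undersample positives; similarity bookkeeping and cutoff scan
    scan = cutoff_scan(positives, list(config.cutoff_grid))
    scan.to_csv(out / "cutoff_scan.csv", index=False)
    assignment, retained_pos = cluster_undersample(positives, config.cluster_cutoff)
    _, mean_before = similarity_stats(_ecfp4_fingerprints(positives))
    _, mean_after = similarity_stats(_ecfp4_fingerprints(retained_pos))
    _, mean_neg = similarity_stats(_ecfp4_fingerprints(negatives))
    pd.DataFrame([
        {"set": "positives_before", "mean_similarity": mean_before},
        {"set": "positives_after", "mean_similarity": mean_after},
        {"set": "negatives", "mean_similarity": mean_neg},
    ]).to_csv(out / "similarity_means.csv", index=False)
    pd.DataFrame([
        {"molecule_id": mid, "cluster": cl,
         "is_representative": assignment.representative_of[cl] == mid}
        for mid, cl in assignment.cluster_of.items()
    ]).to_csv(out / "clusters.csv", index=False)

    n_heat = min(config.heatmap_subsample, len(positives))
    heat_idx = sorted(rng.choice(len(positives), size=n_heat, replace=False))
    heat_records = [positives[i] for i in heat_idx]
    heat_matrix, _ = similarity_stats(_ecfp4_fingerprints(heat_records),
                                      [r.mol.id for r in heat_records])
    heat_matrix.to_frame().to_csv(out / "similarity_heatmap.csv")
    modeling_set = retained_pos + negatives
    bundle.update(cluster_assignment=assignment, retained_positives=retained_pos,
                  similarity_means={"positives_before": mean_before,
                                    "positives_after": mean_after,
                                    "negatives": mean_neg})
    completed.append("undersample")

    # 4. stratified split
    split = stratified_split(modeling_set, config.split_proportions, config.seed)
    membership = [{"molecule_id": mid, "split": name}
                  for name in ("train", "validation", "test")
                  for mid in getattr(split, name)]
    pd.DataFrame(membership).to_csv(out / "split.csv", index=False)
    diversity_summary(split, modeling_set).to_csv(
        out / "diversity_summary.csv", index=False)
    bundle["split"] = split
    completed.append("split")

    # 5. fingerprints for every model family
    by_id = {r.mol.id: r for r in modeling_set}
    ids = {name: list(getattr(split, name)) for name in
           ("train", "validation", "test")}
    labels = {name: np.array([by_id[m].label for m in ids[name]])
              for name in ids}
    features = {
        family: {name: fingerprint_matrix([by_id[m].mol for m in ids[name]],
                                          family)
                 for name in ids}
        for family in config.families
    }
    completed.append("fingerprint")

    # 6. model grid, validation metrics
    algorithms = config.algorithms
    models, val_reports = run_model_grid(
        features, labels, ids, seed=config.seed,
        algorithms=algorithms or ("logistic_regression", "svm", "naive_bayes",
                                  "mlp", "random_forest"),
        families=config.families, grids=config.grids or None)
    val_frame = pd.DataFrame([r.to_row() for r in rank_models(val_reports)])
    val_frame.to_csv(out / "metrics_validation.csv", index=False)
    if config.save_models:
        from .modeling import save_model

        model_dir = out / "models"
        model_dir.mkdir(exist_ok=True)
        for model in models.values():
            save_model(model, model_dir / f"{model.name}.model")
    bundle["models"], bundle["validation_reports"] = models, val_reports
    completed.append("train")

    # 7. top-10 on the test set
    top10 = top_k(val_reports, 10)
    test_reports = []
    for report in top10:
        model = models[report.model_name]
        family = model.spec.fingerprint
        test_reports.append(evaluate(model, features[family]["test"],
                                     labels["test"], ids["test"],
                                     eval_set="test"))
    pd.DataFrame([r.to_row() for r in rank_models(test_reports)]).to_csv(
        out / "metrics_test.csv", index=False)
    from .modeling import score_curves

    roc_tables, pr_tables = [], []
    for report in test_reports:
        _, _, roc_pts, pr_pts = score_curves(report.scores, labels["test"])
        roc_tables.append(roc_pts.assign(model=report.model_name))
        pr_tables.append(pr_pts.assign(model=report.model_name))
    pd.concat(roc_tables).to_csv(out / "roc_curves_test.csv", index=False)
    pd.concat(pr_tables).to_csv(out / "pr_curves_test.csv", index=False)
    bundle["test_reports"] = test_reports
    completed.append("rank")

    # 8. top-5 majority-vote ensemble on the test set
    k = min(5, len(val_reports))
    if k % 2 == 0:  # majority voting needs an odd committee
        k -= 1
    top5_names = [r.model_name for r in top_k(val_reports, k)]
    votes = np.vstack([
        next(t for t in test_reports if t.model_name == name).predictions
        for name in top5_names
    ])
    ensemble_pred = ensemble_vote(votes)
    from .modeling import (accuracy, confusion_from_predictions, mcc,
                           sensitivity, specificity)
    cm = confusion_from_predictions(labels["test"], ensemble_pred)
    ensemble_row = {"model": "ensemble_top5", "set": "test",
                    "Q": accuracy(cm), "SE": sensitivity(cm),
                    "SP": specificity(cm), "MCC": mcc(cm),
                    "members": ";".join(top5_names)}
    pd.DataFrame([ensemble_row]).to_csv(out / "ensemble.csv", index=False)
    bundle["ensemble"] = ensemble_row
    completed.append("ensemble")

    # 9. alert mining, sulfa partition, PCA separation
    alerts = extract_alerts(curated, radii=config.alert_radii,
                            alpha=config.alert_alpha,
                            min_count=config.alert_min_count)
    alerts_table(alerts).to_csv(out / "alerts.csv", index=False)
    sulfa_ids, non_sulfa_ids = sulfa_partition(positives, config.sulfa_pattern)
    pd.DataFrame(
        [{"molecule_id": m, "is_sulfa": True} for m in sulfa_ids]
        + [{"molecule_id": m, "is_sulfa": False} for m in non_sulfa_ids]
    ).to_csv(out / "sulfa_partition.csv", index=False)
    pca_rows, coord_rows = [], []
    sulfa_set = set(sulfa_ids)
    groups = [int(r.mol.id in sulfa_set) for r in positives]
    if min(sum(groups), len(groups) - sum(groups)) >= 3:
        for family in config.families:
            result = pca_separation(positives, groups, family)
            pca_rows.append({"family": family,
                             "silhouette": result["silhouette"],
                             "pc1_var": result["explained_variance_ratio"][0],
                             "pc2_var": result["explained_variance_ratio"][1]})
            for rec, grp, (pc1, pc2) in zip(positives, groups,
                                            result["coordinates"]):
                coord_rows.append({"family": family, "molecule_id": rec.mol.id,
                                   "is_sulfa": bool(grp),
                                   "pc1": pc1, "pc2": pc2})
        pd.DataFrame(pca_rows).to_csv(out / "pca_separation.csv", index=False)
        pd.DataFrame(coord_rows).to_csv(out / "pca_coordinates.csv", index=False)
    bundle["alerts"], bundle["sulfa"] = alerts, (sulfa_ids, non_sulfa_ids)
    bundle["pca"] = pca_rows
    completed.append("alerts")

    # manifest
    config_dict = config.to_dict()
    manifest = {
        "package": "navscreen",
        "version": __version__,
        "seed": config.seed,
        "stages": completed,
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()).hexdigest(),
        "versions": _environment_versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    return bundle


def _environment_versions() -> Dict[str, str]:
    import rdkit
    import sklearn

    return {"numpy": np.__version__, "pandas": pd.__version__,
            "rdkit": rdkit.__version__, "scikit-learn": sklearn.__version__}
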