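"""Run the curation funnel on a molecule CSV and compare the classes.

Stages: parse/canonicalize, deduplicate (median activity per structure),
label at the 30,000 nM IC50 threshold, atom-count + Lipinski filter. Also
reports the Welch t-test comparison of six descriptors between positives
and negatives.
"""

import argparse
from pathlib import Path

import pandas as pd

from navscreen.curation import CurationConfig, compare_descriptors, curate
from navscreen.pipeline import io_read_molecules, io_write_molecules


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--library", type=Path, default=Path("results/library.csv"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--threshold-nM", type=float, default=30_000.0)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    raw = io_read_molecules(args.library, "csv")
    curated, log = curate(raw, CurationConfig(threshold_nM=args.threshold_nM))
    print("curation funnel:")
    print(log)
    io_write_molecules(curated, args.out / "curated.csv")
    pd.DataFrame(log.to_rows()).to_csv(args.out / "curation_log.csv", index=False)

    positives = [r for r in curated if r.label == 1]
    negatives = [r for r in curated if r.label == 0]
    pvals = compare_descriptors(positives, negatives)
    pd.DataFrame([pvals]).to_csv(args.out / "descriptor_ttest.csv", index=False)
    print(f"{len(positives)} positives vs {len(negatives)} negatives")
    print("descriptor Welch t-test p-values (positives vs negatives):")
    for name, p in pvals.items():
        print(f"  {name:8s} p = {p:.3g}")


if __name__ == "__main__":
    main()
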