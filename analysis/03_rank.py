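#!/usr/bin/env python
"""Recurrence filtering and ranking.

Merges dual-control calls per patient (coincidence rule), keeps proteins
changed co-directionally at |fold| > 2 in >= 5 patients from >= 2 independent
runs, averages folds over significantly changed patients only, and ranks by
frequency x |fold|.  Writes results/report.tsv and prints the top of the
ranking.
"""

import argparse
from pathlib import Path

import pandas as pd

from amlproteo.recurrence import recurrence_select


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--comparisons", default="results/comparisons.tsv")
    parser.add_argument("--out", default="results/report.tsv")
    parser.add_argument("--min-patients", type=int, default=5)
    parser.add_argument("--min-runs", type=int, default=2)
    parser.add_argument("--min-fold", type=float, default=2.0)
    parser.add_argument("--annotation", default="results/study/truth.tsv",
                        help="TSV with protein_id and compartment columns "
                             "for the nuclear pass-through flag")
    args = parser.parse_args()

    annotation = None
    if Path(args.annotation).exists():
        ann = pd.read_csv(args.annotation, sep="\t").set_index("protein_id")
        if "compartment" in ann.columns:
            annotation = ann["compartment"] == "nuclear"

    comparisons = pd.read_csv(args.comparisons, sep="\t")
    report = recurrence_select(comparisons, min_patients=args.min_patients,
                               min_runs=args.min_runs, min_fold=args.min_fold,
                               annotation=annotation)
    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    report.to_csv(args.out, sep="\t", index=False, float_format="%.10g")

    print(f"{len(report)} recurrent proteins "
          f"(>= {args.min_patients} patients, >= {args.min_runs} runs, "
          f"|fold| > {args.min_fold})")
    if len(report):
        print(report.head(10).to_string(index=False))


if __name__ == "__main__":
    main()
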