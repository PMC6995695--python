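#!/usr/bin/env python
"""Protein-mRNA integration of the recurrent proteins.

Joins the ranked recurrence report with the DE results (identity join on
shared identifiers), classifies each pair as concordant / discordant /
no-mRNA-change, and reports the concordance rate — the fraction of protein
changes that are transcriptionally mirrored.  Writes
results/concordance.tsv and results/integration_summary.json.
"""

import argparse
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from amlproteo.concordance import build_records, summarise


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--report", default="results/report.tsv")
    parser.add_argument("--de", default="results/de_results.tsv")
    parser.add_argument("--out", default="results")
    args = parser.parse_args()

    report = pd.read_csv(args.report, sep="\t")
    de = pd.read_csv(args.de, sep="\t")
    records = build_records(report, de)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    records.to_csv(out / "concordance.tsv", sep="\t", index=False,
                   float_format="%.10g")

    if records.empty:
        print("no recurrent proteins to integrate")
        return
    s = summarise(records)
    with open(out / "integration_summary.json", "w", encoding="utf-8") as fh:
        json.dump(asdict(s), fh, indent=2)
    print(f"{s.n_records} recurrent proteins integrated with mRNA data:")
    print(f"  concordant      {s.n_concordant}")
    print(f"  discordant      {s.n_discordant}")
    print(f"  no mRNA change  {s.n_no_mrna_change}")
    print(f"  concordance rate {s.concordance_rate:.1f}% "
          f"(prints as {round(s.concordance_rate)}%)")


if __name__ == "__main__":
    main()
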