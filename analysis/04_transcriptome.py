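#!/usr/bin/env python
"""Two-group differential expression on the matched expression matrix.

Per-gene one-way ANOVA of AML vs. control normalized log2 intensities with
signed fold changes; genes pass DE at P < 0.05 and |fold| > 1.5, and carry
the milder mRNA-change flag (P < 0.05, |fold| >= 1.3) used downstream for
concordance.  Writes results/de_results.tsv.
"""

import argparse
from pathlib import Path

from amlproteo.expression import de_filter, de_test
from amlproteo.simulate import read_expression, read_samples


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--study", default="results/study")
    parser.add_argument("--out", default="results/de_results.tsv")
    parser.add_argument("--p", type=float, default=0.05)
    parser.add_argument("--fold", type=float, default=1.5)
    args = parser.parse_args()

    study_dir = Path(args.study)
    matrix = read_expression(study_dir / "expression.tsv")
    groups = read_samples(study_dir / "samples.tsv").set_index(
        "sample_id")["group"]
    results = de_test(matrix, groups, p_max=args.p, de_fold=args.fold)
    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    results.to_csv(args.out, sep="\t", index=False, float_format="%.10g")

    de = de_filter(results, p_max=args.p, min_fold=args.fold)
    print(f"{len(results)} genes tested, {len(de)} DE "
          f"(P < {args.p}, |fold| > {args.fold}), "
          f"{int(results['mrna_change_flag_1p3'].sum())} with the "
          f"mRNA-change flag (|fold| >= 1.3)")


if __name__ == "__main__":
    main()
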