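"""Curated published reference values for the AML nuclear-proteome discovery
cohort (15 FAB-M1 patients vs. normal CD34+ cells).

Two small tables of reported protein-level results are embedded as in-code
data so that the ranking and concordance rules can be exercised against known
answers without any download:

* ``TF_CHANGES`` — the 11 transcription factors reported as frequently
  changed in AML nuclei: frequency (patients out of 15), significant-only
  average protein fold, matched normalized mRNA fold, and whether the mRNA
  change met the ANOVA P < 0.05 and |fold| >= 1.3 rule.
* ``TOP_PROTEINS`` — the ten highest-ranked proteins by frequency x |fold|.

Signed folds follow the package convention: positive = up in AML.
"""

from __future__ import annotations

import pandas as pd

# gene symbol, frequency, protein fold, mRNA fold, mRNA-change flag
_TF_ROWS = [
    ("NFIC",    6,  5.5,  1.5, True),
    ("WT1",     8,  2.9,  5.6, True),
    ("CEBPA",   7,  2.9,  1.7, True),
    ("ILF3",    8, -2.4, -1.2, False),
    ("ILF2",    7, -2.7, -1.2, False),
    ("HNRNPDL", 11, -3.3, -1.0, False),
    ("BCL11A",  8, -3.3, -1.4, True),
    ("DAZAP1",  10, -3.4, -1.2, False),
    ("TARDBP",  9, -3.8,  1.3, True),
    ("MYEF2",   10, -5.4, -3.7, True),
    ("HMGA2",   14, -5.9, -3.0, True),
]

TF_CHANGES = pd.DataFrame(
    _TF_ROWS,
    columns=["gene_symbol", "frequency", "protein_fold", "mrna_fold",
             "mrna_change_flag"],
)

# gene symbol, frequency, average fold, published frequency x fold product
_TOP_ROWS = [
    ("HMGA2",  14, -6.0, 84.7),
    ("ANXA1",  11,  6.3, 69.6),
    ("PTRF",   11, -5.7, 63.4),
    ("S100A4", 11,  5.5, 60.5),
    ("LSP1",   13, -4.2, 54.8),
    ("MYEF2",  10, -5.4, 54.1),
    ("MPO",     9,  5.3, 48.4),
    ("ANXA4",  11,  4.20, 46.2),
    ("S100A6", 11,  3.89, 42.8),
    ("FLNB",   13, -3.3, 42.7),
]

TOP_PROTEINS = pd.DataFrame(
    _TOP_ROWS,
    columns=["gene_symbol", "frequency", "avg_fold", "published_score"],
)

# Rows whose published product reconciles exactly with the printed frequency
# and fold (others were evidently computed from unrounded folds).
RECONCILING_TOP_ROWS = ("S100A4", "ANXA4", "S100A6")
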