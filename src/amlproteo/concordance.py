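"""Protein-mRNA integration: join recurrent protein changes with
differential-expression results, classify concordance, and summarise
agreement rates.

A protein change is *concordant* when the matched gene carries the mRNA-change
flag (ANOVA P < 0.05 and |fold| >= 1.3) and the mRNA fold shares the protein
fold's direction; *discordant* when flagged but opposite in direction; and
*no_mrna_change* otherwise.  Concordance quantifies how far nuclear protein
changes in AML are transcriptionally driven.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

CONCORDANT = "concordant"
DISCORDANT = "discordant"
NO_MRNA_CHANGE = "no_mrna_change"

RECORD_COLUMNS = ["protein_id", "gene_id", "protein_fold", "mrna_fold",
                  "mrna_change_flag", "class"]


class IntegrationError(ValueError):
    pass


def concordance_classify(protein_fold: float, mrna_fold: float,
                         mrna_change_flag: bool) -> str:
    """Classify one protein-mRNA pair; total and exclusive over the three
    classes."""
    if not (np.isfinite(protein_fold) and np.isfinite(mrna_fold)):
        raise IntegrationError("folds must be finite")
    if not mrna_change_flag:
        return NO_MRNA_CHANGE
    if np.sign(protein_fold) == np.sign(mrna_fold):
        return CONCORDANT
    return DISCORDANT


def build_records(report: pd.DataFrame, de_results: pd.DataFrame,
                  mapping: pd.DataFrame | None = None) -> pd.DataFrame:
    """Join the recurrent-protein report with DE results.

    The protein -> gene join defaults to identity on shared identifiers; a
    ``mapping`` frame (protein_id, gene_id) overrides it.  Unmapped proteins
    are excluded from the records (and from the rates) but their count is
    recoverable as ``len(report) - len(records)``.
    """
    if mapping is not None:
        joined = report.merge(mapping[["protein_id", "gene_id"]], on="protein_id")
    else:
        joined = report.copy()
        joined["gene_id"] = joined["protein_id"]
    de = de_results.set_index("gene_id")
    joined = joined[joined["gene_id"].isin(de.index)]
    records = pd.DataFrame({
        "protein_id": joined["protein_id"].to_numpy(),
        "gene_id": joined["gene_id"].to_numpy(),
        "protein_fold": joined["avg_fold"].to_numpy(float),
        "mrna_fold": de.loc[joined["gene_id"], "signed_fold"].to_numpy(float),
        "mrna_change_flag": de.loc[joined["gene_id"],
                                   "mrna_change_flag_1p3"].to_numpy(bool),
    })
    records["class"] = [
        concordance_classify(p, m, f)
        for p, m, f in zip(records["protein_fold"], records["mrna_fold"],
                           records["mrna_change_flag"])
    ]
    return records[RECORD_COLUMNS]


def concordance_rate(records: pd.DataFrame) -> tuple[float, Fraction]:
    """Percentage of records classified concordant, with the exact fraction.

    Returns ``(percentage, Fraction)``; the percentage prints to the nearest
    integer in reports.  Order-invariant; empty input is an error.
    """
    if len(records) == 0:
        raise IntegrationError("concordance_rate: no records")
    n_conc = int((records["class"] == CONCORDANT).sum())
    frac = Fraction(n_conc, len(records))
    return 100.0 * n_conc / len(records), frac


@dataclass(frozen=True)
class IntegrationSummary:
    n_records: int
    n_concordant: int
    n_discordant: int
    n_no_mrna_change: int
    concordance_rate: float   # percent

    @property
    def agreement_rate(self) -> float:
        return self.concordance_rate


def summarise(records: pd.DataFrame) -> IntegrationSummary:
    counts = records["class"].value_counts()
    rate, _ = concordance_rate(records)
    summary = IntegrationSummary(
        n_records=len(records),
        n_concordant=int(counts.get(CONCORDANT, 0)),
        n_discordant=int(counts.get(DISCORDANT, 0)),
        n_no_mrna_change=int(counts.get(NO_MRNA_CHANGE, 0)),
        concordance_rate=rate,
    )
    assert (summary.n_concordant + summary.n_discordant +
            summary.n_no_mrna_change) == summary.n_records
    return summary


def protein_mrna_correlation(protein_values, mrna_values,
                             confidence: float = 0.95):
    """Pearson correlation of paired protein and mRNA measurements with a
    Fisher-z confidence interval.

    Requires n >= 3 and non-degenerate variance in both vectors.  Returns
    ``(r, (lower, upper))``.
    """
    x = np.asarray(protein_values, dtype=float)
    y = np.asarray(mrna_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise IntegrationError("need paired 1-D vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise IntegrationError("correlation undefined for zero-variance input")
    r = float(stats.pearsonr(x, y).statistic)
    if abs(r) >= 1.0 or len(x) <= 3:
        return r, (-1.0, 1.0) if len(x) <= 3 else (r, r)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(len(x) - 3)
    zcrit = stats.norm.ppf(0.5 + confidence / 2.0)
    lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    return r, (float(lo), float(hi))
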