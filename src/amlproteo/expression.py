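"""Two-group differential expression on a normalized log2 expression matrix.

Per gene, a one-way fixed-effects ANOVA (computed directly from sums of
squares; with two groups the F statistic is the square of the equal-variance
t statistic) plus a signed linear fold change from the difference of group
means on the log2 scale.  Two flags are derived per gene: the DE flag used to
select differentially expressed genes (P < 0.05 and |fold| > 1.5, strict) and
the milder mRNA-change flag feeding the concordance rule (P < 0.05 and
|fold| >= 1.3, inclusive).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .quant import signed_fold

logger = logging.getLogger(__name__)

DE_COLUMNS = ["gene_id", "p_value", "signed_fold", "de_flag_1p5",
              "mrna_change_flag_1p3"]


class ExpressionError(ValueError):
    pass


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA from sums of squares.

    Returns ``(F, p)``.  Constant data (zero within- and between-group sum of
    squares) gives p = 1 by convention; zero within-group variance with a
    real group difference gives p = 0.
    """
    k = len(groups)
    n = sum(len(g) for g in groups)
    if k < 2 or n - k < 1:
        raise ExpressionError("ANOVA needs >=2 groups and residual df >= 1")
    grand = sum(g.sum() for g in groups) / n
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_within <= 0:
        return (np.inf, 0.0) if ss_between > 0 else (0.0, 1.0)
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return float(f), float(stats.f.sf(f, k - 1, n - k))


def welch_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Welch's unequal-variance alternative (two groups: Welch's t squared)."""
    if len(groups) != 2:
        raise ExpressionError("welch variant implemented for two groups")
    a, b = groups
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t * t), float(p)


def de_test(matrix: pd.DataFrame, groups: pd.Series, *,
            case: str = "AML", control: str = "control",
            p_max: float = 0.05, de_fold: float = 1.5,
            concord_fold: float = 1.3, variant: str = "anova") -> pd.DataFrame:
    """Differential-expression test for every gene of a genes x samples matrix.

    ``groups`` labels each sample column as case or control; both groups need
    n >= 2.  The signed fold is ``signed_fold(mean_case - mean_control)``, the
    same sign convention as the proteomic stage.  Constant genes are assigned
    p = 1 and logged.
    """
    for label in (case, control):
        if (groups == label).sum() < 2:
            raise ExpressionError(f"group {label!r} needs n >= 2")
    missing = [s for s in matrix.columns if s not in groups.index]
    if missing:
        raise ExpressionError(f"samples without group label: {missing[:5]}")
    values = matrix.to_numpy(float)
    if not np.isfinite(values).all():
        raise ExpressionError("expression matrix contains non-finite values")

    case_cols = [s for s in matrix.columns if groups[s] == case]
    ctrl_cols = [s for s in matrix.columns if groups[s] == control]
    a = matrix[case_cols].to_numpy(float)
    b = matrix[ctrl_cols].to_numpy(float)

    test = anova_oneway if variant == "anova" else welch_anova
    n_constant = 0
    p_values = np.empty(len(matrix))
    for i in range(len(matrix)):
        _, p = test([a[i], b[i]])
        if np.ptp(values[i]) == 0:
            n_constant += 1
        p_values[i] = p
    if n_constant:
        logger.warning("de_test: %d constant genes assigned p=1", n_constant)

    diff = a.mean(axis=1) - b.mean(axis=1)
    folds = signed_fold(diff)
    out = pd.DataFrame({
        "gene_id": matrix.index,
        "p_value": p_values,
        "signed_fold": folds,
        "de_flag_1p5": (p_values < p_max) & (np.abs(folds) > de_fold),
        "mrna_change_flag_1p3": (p_values < p_max) & (np.abs(folds) >= concord_fold),
    })
    return out.reset_index(drop=True)


def de_filter(results: pd.DataFrame, p_max: float = 0.05,
              min_fold: float = 1.5) -> pd.DataFrame:
    """Select DE genes: p strictly below ``p_max`` and |fold| strictly above
    ``min_fold`` (a gene at exactly the fold threshold is excluded)."""
    keep = (results["p_value"] < p_max) & \
           (np.abs(results["signed_fold"]) > min_fold)
    return results[keep].reset_index(drop=True)
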