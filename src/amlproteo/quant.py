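"""Per-run isobaric-tag quantitation: peptide-ratio normalization, the
control-derived empirical null with its confidence limits, peptide-to-protein
rollup, and per-comparison significance calls.

The significance model is distribution-free.  Within one run, peptide log2
ratios between the two CD34+ control channels measure pure technical
variation; their empirical (1-c)/2 and 1-(1-c)/2 quantiles form intra-run
confidence limits at level ``c`` (0.90 by default).  A protein's aggregated
sample:control log2 ratio is called significant when it falls strictly
outside the limits of its own run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COMPARISON_COLUMNS = ["run_id", "protein_id", "sample_id", "control_id",
                      "log2_ratio", "n_peptides", "significant", "direction"]


class QuantError(ValueError):
    pass


class InsufficientNullError(QuantError):
    """Too few control:control ratios for a per-run null; pool runs instead."""


# ---------------------------------------------------------------------------
# normalization

def normalize_run(records: pd.DataFrame, method: str = "median"):
    """Center peptide log2 ratios per comparison channel pair.

    With ``method='median'`` each (run_id, sample_id, control_id) group is
    shifted so its median log2 ratio is zero, absorbing systematic labelling
    or loading bias; ``'none'`` is the identity.  Non-finite ratios are
    dropped (count logged).  Returns ``(table, shifts)`` where ``shifts`` maps
    each channel pair to the subtracted median.
    """
    if records.empty:
        raise QuantError("normalize_run: empty run")
    if method not in ("median", "none"):
        raise QuantError(f"unknown normalization method {method!r}")

    finite = np.isfinite(records["log2_ratio"].to_numpy(float))
    if not finite.all():
        logger.warning("normalize_run: rejected %d non-finite ratios",
                       int((~finite).sum()))
        records = records[finite]
    if records.empty:
        raise QuantError("normalize_run: no finite ratios left")

    keys = ["run_id", "sample_id", "control_id"]
    if method == "none":
        shifts = records.groupby(keys, sort=False)["log2_ratio"].median() * 0.0
        return records.copy(), shifts

    med = records.groupby(keys, sort=False)["log2_ratio"].transform("median")
    out = records.copy()
    out["log2_ratio"] = records["log2_ratio"] - med
    shifts = records.groupby(keys, sort=False)["log2_ratio"].median()
    return out, shifts


# ---------------------------------------------------------------------------
# empirical null

@dataclass(frozen=True)
class ControlNull:
    """Empirical null for one run, built from control:control peptide ratios.

    ``lower``/``upper`` are the symmetric empirical quantiles that bracket a
    ``confidence`` fraction of the null ratios (linear-interpolation quantile
    definition, numpy default).
    """

    run_id: str
    null_ratios: np.ndarray
    confidence: float = 0.90
    lower: float = field(init=False)
    upper: float = field(init=False)

    def __post_init__(self) -> None:
        alpha = (1.0 - self.confidence) / 2.0
        lo, hi = np.quantile(self.null_ratios, [alpha, 1.0 - alpha])
        object.__setattr__(self, "lower", float(lo))
        object.__setattr__(self, "upper", float(hi))

    @property
    def n(self) -> int:
        return int(len(self.null_ratios))


def null_source_mask(records: pd.DataFrame, control_ids) -> pd.Series:
    """Rows whose 'sample' channel is itself a control: control:control
    comparisons, the empirical-null source."""
    controls = set(control_ids)
    return records["sample_id"].isin(controls) & records["control_id"].isin(controls)


def build_control_null(null_ratios, confidence: float = 0.90,
                       run_id: str = "", min_null: int = 50) -> ControlNull:
    """Build the intra-run empirical null from control:control peptide ratios.

    Raises :class:`InsufficientNullError` when fewer than ``min_null`` finite
    ratios are available; callers should then fall back to a null pooled
    across runs (:func:`build_pooled_null`).
    """
    arr = np.asarray(null_ratios, dtype=float)
    arr = arr[np.isfinite(arr)]
    if len(arr) < min_null:
        raise InsufficientNullError(
            f"run {run_id or '?'}: only {len(arr)} control:control ratios "
            f"(minimum {min_null}); pool null ratios across runs instead"
        )
    if not 0.0 < confidence < 1.0:
        raise QuantError("confidence must lie in (0, 1)")
    return ControlNull(run_id=run_id, null_ratios=arr, confidence=confidence)


def build_pooled_null(runs: dict[str, pd.DataFrame], control_ids,
                      confidence: float = 0.90, min_null: int = 50) -> ControlNull:
    """Fallback null pooling control:control ratios over all runs."""
    pools = [run[null_source_mask(run, control_ids)]["log2_ratio"].to_numpy(float)
             for run in runs.values()]
    pooled = np.concatenate(pools) if pools else np.empty(0)
    return build_control_null(pooled, confidence=confidence, run_id="pooled",
                              min_null=min_null)


# ---------------------------------------------------------------------------
# rollup and calling

def aggregate_protein(records: pd.DataFrame, estimator: str = "median",
                      min_peptides: int = 1) -> pd.DataFrame:
    """Roll peptides up to protein-level comparisons.

    One output row per (run, protein, sample, control): ``log2_ratio`` is the
    median (default; robust to a single outlier peptide) or mean over that
    comparison's peptides, with the peptide count recorded.  Proteins with
    fewer than ``min_peptides`` observations are absent from the output.
    """
    if estimator not in ("median", "mean"):
        raise QuantError(f"unknown estimator {estimator!r}")
    if records.empty:
        return pd.DataFrame(columns=COMPARISON_COLUMNS)
    keys = ["run_id", "protein_id", "sample_id", "control_id"]
    grouped = records.groupby(keys, sort=False)["log2_ratio"]
    out = grouped.agg(log2_ratio=estimator, n_peptides="size").reset_index()
    out = out[out["n_peptides"] >= min_peptides].reset_index(drop=True)
    out["significant"] = False
    out["direction"] = 0
    return out[COMPARISON_COLUMNS]


def call_significance(comparisons: pd.DataFrame, null: ControlNull) -> pd.DataFrame:
    """Flag protein comparisons falling strictly outside the null limits.

    A ratio exactly on a limit is not significant (deterministic ties).
    ``direction`` is the ratio's sign for significant rows, 0 otherwise.
    """
    if comparisons.empty:
        return comparisons.copy()
    runs = set(comparisons["run_id"].unique())
    if null.run_id not in ("", "pooled") and runs - {null.run_id}:
        raise QuantError(
            f"null built for run {null.run_id!r} applied to runs {sorted(runs)}"
        )
    out = comparisons.copy()
    r = out["log2_ratio"].to_numpy(float)
    sig = (r < null.lower) | (r > null.upper)
    out["significant"] = sig
    out["direction"] = np.where(sig, np.sign(r).astype(int), 0)
    return out


def signed_fold(log2_ratio):
    """Signed linear fold convention: +2**r for r >= 0, -2**(-r) for r < 0.

    Magnitudes are symmetric around +/-1 (|fold| >= 1 always); positive folds
    are up in AML vs. control, negative folds down.
    """
    r = np.asarray(log2_ratio, dtype=float)
    if not np.isfinite(r).all():
        raise QuantError("signed_fold: non-finite log2 ratio")
    out = np.where(r >= 0, np.power(2.0, r), -np.power(2.0, -r))
    return float(out) if np.isscalar(log2_ratio) or out.ndim == 0 else out


def log2_from_signed_fold(fold):
    """Inverse of :func:`signed_fold`."""
    f = np.asarray(fold, dtype=float)
    if (np.abs(f) < 1).any():
        raise QuantError("signed fold magnitudes are >= 1 by convention")
    out = np.where(f >= 0, np.log2(np.abs(f)), -np.log2(np.abs(f)))
    return float(out) if np.isscalar(fold) or out.ndim == 0 else out


# ---------------------------------------------------------------------------
# per-run driver

def process_runs(runs: dict[str, pd.DataFrame], control_ids, *,
                 confidence: float = 0.90, estimator: str = "median",
                 normalize: str = "median", min_null: int = 50,
                 min_peptides: int = 1, null_level: str = "peptide"):
    """Quantify every run: normalize, build its null, roll up, call.

    ``null_level='peptide'`` (default) builds limits from control:control
    peptide ratios; ``'protein'`` first rolls the null-source peptides up to
    protein ratios with the same estimator, matching the aggregation level of
    the tested comparisons.  Runs without enough null ratios fall back to a
    pooled null across runs.  Returns ``(comparisons, nulls)``.
    """
    if null_level not in ("peptide", "protein"):
        raise QuantError(f"unknown null_level {null_level!r}")
    normalized: dict[str, pd.DataFrame] = {}
    for run_id, table in runs.items():
        normalized[run_id], _ = normalize_run(table, method=normalize)

    nulls: dict[str, ControlNull] = {}
    pooled = None
    results = []
    for run_id, table in normalized.items():
        is_null = null_source_mask(table, control_ids)
        null_rows = table[is_null]
        if null_level == "protein":
            null_values = aggregate_protein(null_rows, estimator=estimator,
                                            min_peptides=min_peptides
                                            )["log2_ratio"].to_numpy(float)
        else:
            null_values = null_rows["log2_ratio"].to_numpy(float)
        try:
            null = build_control_null(null_values, confidence=confidence,
                                      run_id=run_id, min_null=min_null)
        except InsufficientNullError:
            if pooled is None:
                pooled = build_pooled_null(normalized, control_ids,
                                           confidence=confidence,
                                           min_null=min_null)
            logger.warning("run %s: sparse null, using pooled null", run_id)
            null = pooled
        nulls[run_id] = null

        tested = aggregate_protein(table[~is_null], estimator=estimator,
                                   min_peptides=min_peptides)
        results.append(call_significance(tested, null))

    comparisons = (pd.concat(results, ignore_index=True) if results
                   else pd.DataFrame(columns=COMPARISON_COLUMNS))
    return comparisons, nulls
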