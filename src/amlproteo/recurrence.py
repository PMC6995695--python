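"""Cross-patient recurrence: dual-control coincidence merging, the
recurrence filter, significant-only fold averaging and frequency x |fold|
ranking.

Discovery logic: a protein counts as changed in a patient only when the
evidence is coincident — in runs carrying two CD34+ control channels both
sample:control comparisons must be significant in the same direction.  A
protein survives discovery when it changed co-directionally, beyond a minimum
fold, in enough patients observed across enough independent MS runs.
Surviving proteins are ranked by the product of their frequency of
observation and the magnitude of their average fold change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .quant import signed_fold

VERDICT_COLUMNS = ["protein_id", "patient_id", "run_id", "changed",
                   "direction", "log2_ratio"]
REPORT_COLUMNS = ["protein_id", "frequency", "n_runs_supporting", "avg_fold",
                  "score", "nuclear"]


class CoincidenceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# coincidence merging

def coincidence_merge(comparisons: pd.DataFrame) -> pd.DataFrame:
    """Merge per-control significance calls into per-patient verdicts.

    For each (protein, patient, run): with two control comparisons the patient
    verdict is *changed* only if both are significant with the same direction
    (consensus log2 ratio = mean of the two); with a single control the
    comparison's own call stands.  More than two comparisons for one
    patient/run is a design error.
    """
    if comparisons.empty:
        return pd.DataFrame(columns=VERDICT_COLUMNS)

    keys = ["protein_id", "sample_id", "run_id"]
    sizes = comparisons.groupby(keys, sort=False)["log2_ratio"].size()
    if (sizes > 2).any():
        bad = sizes[sizes > 2].index[0]
        raise CoincidenceError(
            f">2 control comparisons for protein/patient/run {bad}; "
            "runs carry at most two control channels"
        )

    g = comparisons.groupby(keys, sort=False)
    merged = g.agg(
        n=("log2_ratio", "size"),
        log2_ratio=("log2_ratio", "mean"),
        n_sig=("significant", "sum"),
        dir_min=("direction", "min"),
        dir_max=("direction", "max"),
    ).reset_index()

    coincident = (merged["n_sig"] == merged["n"]) & (merged["dir_min"] ==
                                                     merged["dir_max"])
    merged["changed"] = coincident
    merged["direction"] = np.where(coincident, merged["dir_max"], 0).astype(int)
    merged = merged.rename(columns={"sample_id": "patient_id"})
    return merged[VERDICT_COLUMNS]


def merge_patient_runs(verdicts: pd.DataFrame) -> pd.DataFrame:
    """Collapse verdicts so each (protein, patient) counts once.

    A patient measured in several runs is *changed* if changed in any run;
    if changed runs disagree in direction the patient is dropped for that
    protein.  The consensus log2 ratio averages the changed runs' ratios and
    ``runs`` keeps the supporting run ids.
    """
    if verdicts.empty:
        out = pd.DataFrame(columns=VERDICT_COLUMNS + ["runs"])
        return out.drop(columns=["run_id"])

    rows = []
    for (protein_id, patient_id), grp in verdicts.groupby(
            ["protein_id", "patient_id"], sort=False):
        changed = grp[grp["changed"]]
        if changed.empty:
            rows.append({"protein_id": protein_id, "patient_id": patient_id,
                         "changed": False, "direction": 0,
                         "log2_ratio": grp["log2_ratio"].mean(), "runs": ()})
            continue
        directions = set(changed["direction"])
        if len(directions) > 1:  # contradictory runs: drop the patient
            continue
        rows.append({
            "protein_id": protein_id, "patient_id": patient_id,
            "changed": True, "direction": directions.pop(),
            "log2_ratio": changed["log2_ratio"].mean(),
            "runs": tuple(sorted(changed["run_id"].unique())),
        })
    return pd.DataFrame(rows, columns=["protein_id", "patient_id", "changed",
                                       "direction", "log2_ratio", "runs"])


# ---------------------------------------------------------------------------
# recurrence filter

def recurrence_select(verdicts: pd.DataFrame, min_patients: int = 5,
                      min_runs: int = 2, min_fold: float = 2.0,
                      annotation: pd.Series | None = None,
                      fold_average: str = "arithmetic") -> pd.DataFrame:
    """Apply the recurrence filter and rank the survivors.

    A protein is retained when, in one shared direction, it changed with
    |fold| strictly greater than ``min_fold`` in at least ``min_patients``
    patients whose supporting evidence spans at least ``min_runs`` distinct
    MS runs.  ``annotation`` (protein_id -> bool) passes the nuclear
    designation through.  Output is sorted by ``score`` descending.
    """
    merged = merge_patient_runs(coincidence_merge_if_needed(verdicts))

    records = []
    if not merged.empty:
        log2_min = np.log2(min_fold)
        for protein_id, grp in merged.groupby("protein_id", sort=False):
            qualifying = grp[grp["changed"] &
                             (np.abs(grp["log2_ratio"]) > log2_min)]
            if qualifying.empty:
                continue
            best = None
            for direction in sorted(set(qualifying["direction"])):
                sub = qualifying[qualifying["direction"] == direction]
                runs = set()
                for r in sub["runs"]:
                    runs.update(r)
                if len(sub) >= min_patients and len(runs) >= min_runs:
                    cand = (len(sub), direction, sub, runs)
                    if best is None or cand[0] > best[0]:
                        best = cand
                    elif cand[0] == best[0]:
                        best = None  # tie between directions: ambiguous, drop
                        break
            if best is None:
                continue
            frequency, direction, sub, runs = best
            fold = average_fold(sub, method=fold_average)
            records.append({
                "protein_id": protein_id,
                "frequency": frequency,
                "n_runs_supporting": len(runs),
                "avg_fold": fold,
                "score": ranking_score(frequency, fold),
                "nuclear": bool(annotation.get(protein_id, False))
                if annotation is not None else False,
            })

    report = pd.DataFrame(records, columns=REPORT_COLUMNS)
    return report.sort_values(["score", "protein_id"],
                              ascending=[False, True]).reset_index(drop=True)


def coincidence_merge_if_needed(table: pd.DataFrame) -> pd.DataFrame:
    """Accept either raw protein comparisons or already-merged verdicts."""
    if "patient_id" in table.columns and "changed" in table.columns:
        return table
    return coincidence_merge(table)


def average_fold(verdicts: pd.DataFrame, method: str = "arithmetic") -> float:
    """Average fold over changed patients only (signed linear scale).

    The arithmetic mean of signed linear folds reproduces the published
    frequency x fold products exactly; a geometric mean (on |log2|, sign
    restored) is available for sensitivity analysis.  Mixed directions are a
    contract violation — co-directionality is enforced upstream.
    """
    changed = verdicts[verdicts["changed"]] if "changed" in verdicts.columns \
        else verdicts
    if changed.empty:
        raise CoincidenceError("average_fold: no changed verdicts")
    directions = set(np.sign(changed["log2_ratio"]).astype(int)) - {0}
    if len(directions) > 1:
        raise CoincidenceError("average_fold: mixed directions")
    folds = signed_fold(changed["log2_ratio"].to_numpy(float))
    if method == "arithmetic":
        return float(np.mean(folds))
    if method == "geometric":
        sign = np.sign(folds[0])
        return float(sign * 2 ** np.mean(np.abs(changed["log2_ratio"])))
    raise CoincidenceError(f"unknown fold average {method!r}")


def ranking_score(frequency: int, avg_fold: float) -> float:
    """Frequency of observation times magnitude of change (direction-free)."""
    if frequency < 0:
        raise CoincidenceError("frequency must be >= 0")
    return float(frequency * abs(avg_fold))
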