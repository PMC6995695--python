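"""Coincidence merging, the recurrence filter (with an independent
enumeration oracle) and frequency x |fold| ranking."""

import numpy as np
import pandas as pd
import pytest

from amlproteo.recurrence import (CoincidenceError, average_fold,
                                  coincidence_merge, ranking_score,
                                  recurrence_select)
from conftest import make_comparisons


# ---------------------------------------------------------------------------
# independent oracle: plain-loop enumeration of the three filter rules

def oracle_recurrence(verdicts, min_patients, min_runs, min_fold):
    """Brute-force recurrence filter over merged patient verdicts."""
    out = {}
    log2_min = np.log2(min_fold)
    for protein_id in sorted(set(verdicts["protein_id"])):
        rows = verdicts[verdicts["protein_id"] == protein_id]
        patients = {}
        for patient_id in set(rows["patient_id"]):
            prows = rows[rows["patient_id"] == patient_id]
            ch = prows[prows["changed"]]
            if len(ch) == 0:
                continue
            dirs = set(ch["direction"])
            if len(dirs) > 1:
                continue  # contradictory runs: patient dropped
            patients[patient_id] = (dirs.pop(),
                                    float(np.mean(ch["log2_ratio"])),
                                    set(ch["run_id"]))
        best = None
        tie = False
        for d in (-1, 1):
            qual = {p: v for p, v in patients.items()
                    if v[0] == d and abs(v[1]) > log2_min}
            runs = set().union(*(v[2] for v in qual.values())) if qual else set()
            if len(qual) >= min_patients and len(runs) >= min_runs:
                if best is None or len(qual) > len(best[0]):
                    best, tie = (qual, runs), False
                elif len(qual) == len(best[0]):
                    tie = True
        if best is None or tie:
            continue
        qual, runs = best
        folds = [(2 ** r if r >= 0 else -(2 ** -r)) for _, r, _ in qual.values()]
        avg = float(np.mean(folds))
        out[protein_id] = (len(qual), len(runs), avg, len(qual) * abs(avg))
    return out


def random_verdicts(rng, n_proteins, n_patients=15, n_runs=3, p_row=0.6,
                    p_changed=0.5):
    rows = []
    for i in range(n_proteins):
        for j in range(n_patients):
            for k in range(rng.integers(1, n_runs + 1)):
                if rng.random() > p_row:
                    continue
                changed = rng.random() < p_changed
                direction = int(rng.choice([-1, 1])) if changed else 0
                mag = float(rng.uniform(0.1, 3.0))
                ratio = direction * mag if changed else rng.normal(0, 0.3)
                rows.append({"protein_id": f"P{i}", "patient_id": f"A{j}",
                             "run_id": f"run{k + 1}", "changed": changed,
                             "direction": direction, "log2_ratio": ratio})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------

class TestCoincidenceMerge:
    def pair(self, r1, s1, r2, s2):
        return make_comparisons([
            ("run1", "P1", "AML01", "CD34_1", r1, s1),
            ("run1", "P1", "AML01", "CD34_2", r2, s2),
        ])

    def test_both_significant_same_direction_is_changed(self):
        v = coincidence_merge(self.pair(1.5, True, 1.1, True))
        row = v.iloc[0]
        assert row["changed"] and row["direction"] == 1
        assert row["log2_ratio"] == pytest.approx(1.3)  # consensus = mean

    def test_contradictory_directions_not_changed(self):
        v = coincidence_merge(self.pair(1.5, True, -1.5, True))
        assert not v["changed"].iloc[0]

    def test_one_nonsignificant_control_not_changed(self):
        v = coincidence_merge(self.pair(1.5, True, 0.2, False))
        assert not v["changed"].iloc[0]

    def test_single_control_call_stands(self):
        v = coincidence_merge(make_comparisons(
            [("run1", "P1", "AML01", "CD34_1", -1.4, True)]))
        assert v["changed"].iloc[0] and v["direction"].iloc[0] == -1

    def test_three_comparisons_rejected(self):
        bad = make_comparisons([
            ("run1", "P1", "AML01", f"CD34_{i}", 1.0, True) for i in range(3)])
        with pytest.raises(CoincidenceError):
            coincidence_merge(bad)


class TestRecurrenceSelect:
    def verdicts(self, n_patients, runs, ratio=1.6):
        rows = []
        for i in range(n_patients):
            rows.append({"protein_id": "P1", "patient_id": f"A{i}",
                         "run_id": runs[i % len(runs)], "changed": True,
                         "direction": 1, "log2_ratio": ratio})
        return pd.DataFrame(rows)

    def test_below_min_patients_excluded(self):
        assert recurrence_select(self.verdicts(4, ["run1", "run2"])).empty

    def test_single_run_excluded_despite_frequency(self):
        assert recurrence_select(self.verdicts(6, ["run1"])).empty

    def test_qualifying_protein_retained_with_score(self):
        report = recurrence_select(self.verdicts(6, ["run1", "run2"]))
        assert list(report["protein_id"]) == ["P1"]
        row = report.iloc[0]
        fold = 2 ** 1.6
        assert row["frequency"] == 6 and row["n_runs_supporting"] == 2
        assert row["avg_fold"] == pytest.approx(fold)
        assert row["score"] == pytest.approx(6 * fold)

    def test_fold_threshold_is_strict(self):
        # |fold| exactly 2 (log2 ratio = 1) does not qualify
        assert recurrence_select(self.verdicts(6, ["run1", "run2"],
                                               ratio=1.0)).empty

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        verdicts = random_verdicts(rng, n_proteins=12)
        report = recurrence_select(verdicts).set_index("protein_id")
        expected = oracle_recurrence(verdicts, 5, 2, 2.0)
        assert set(report.index) == set(expected)
        for pid, (freq, n_runs, avg, score) in expected.items():
            row = report.loc[pid]
            assert row["frequency"] == freq
            assert row["n_runs_supporting"] == n_runs
            assert row["avg_fold"] == pytest.approx(avg)
            assert row["score"] == pytest.approx(score)

    @pytest.mark.parametrize("stricter", [
        {"min_patients": 7}, {"min_runs": 3}, {"min_fold": 3.0}])
    def test_raising_any_threshold_never_adds_proteins(self, stricter):
        rng = np.random.default_rng(99)
        verdicts = random_verdicts(rng, n_proteins=15)
        base = set(recurrence_select(verdicts)["protein_id"])
        strict = set(recurrence_select(verdicts, **stricter)["protein_id"])
        assert strict <= base


class TestFoldAveraging:
    def changed(self, ratios):
        return pd.DataFrame({
            "protein_id": "P1",
            "patient_id": [f"A{i}" for i in range(len(ratios))],
            "changed": True,
            "log2_ratio": ratios,
        })

    def test_singleton(self):
        assert average_fold(self.changed([np.log2(3.0)])) == pytest.approx(3.0)

    def test_mean_of_signed_folds(self):
        # folds +5 and +6 average to +5.5 on the signed linear scale
        out = average_fold(self.changed([np.log2(5), np.log2(6)]))
        assert out == pytest.approx(5.5)

    def test_downregulated_sign_preserved(self):
        out = average_fold(self.changed([-np.log2(5), -np.log2(6)]))
        assert out == pytest.approx(-5.5)

    def test_mixed_directions_rejected(self):
        with pytest.raises(CoincidenceError):
            average_fold(self.changed([1.5, -1.5]))

    def test_geometric_alternative(self):
        out = average_fold(self.changed([1.0, 3.0]), method="geometric")
        assert out == pytest.approx(4.0)  # 2**mean([1,3])


class TestRankingScore:
    @pytest.mark.parametrize("freq,fold,expected", [
        (11, 5.5, 60.5),   # frequency x magnitude, direction-free
        (11, 4.20, 46.2),
        (14, -6.05, 84.7),
        (0, 9.9, 0.0),
    ])
    def test_products(self, freq, fold, expected):
        assert ranking_score(freq, fold) == pytest.approx(expected)

    def test_negative_frequency_rejected(self):
        with pytest.raises(CoincidenceError):
            ranking_score(-1, 2.0)
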