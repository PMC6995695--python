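"""Per-run quantitation: normalization, the control-derived empirical null,
peptide rollup, significance calling and the signed-fold convention."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from amlproteo.quant import (ControlNull, InsufficientNullError, QuantError,
                             aggregate_protein, build_control_null,
                             call_significance, log2_from_signed_fold,
                             normalize_run, signed_fold)


def peptide_table(ratios, run="run1", sample="AML01", control="CD34_1"):
    return pd.DataFrame({
        "run_id": run,
        "peptide_id": [f"pep{i}" for i in range(len(ratios))],
        "protein_id": "P1",
        "sample_id": sample,
        "control_id": control,
        "log2_ratio": np.asarray(ratios, dtype=float),
    })


def sort_quantile_oracle(values, q):
    """Independent linear-interpolation quantile by explicit sort-and-index."""
    xs = sorted(values)
    pos = q * (len(xs) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    return xs[lo] + (pos - lo) * (xs[hi] - xs[lo])


class TestNormalizeRun:
    def test_median_shift_recovered(self):
        base = np.linspace(-1, 1, 21)
        out, shifts = normalize_run(peptide_table(base + 0.7), method="median")
        assert np.median(out["log2_ratio"]) == pytest.approx(0.0, abs=1e-12)
        assert shifts.iloc[0] == pytest.approx(0.7)

    def test_idempotent_on_centered_table(self):
        table = peptide_table(np.linspace(-1, 1, 21))
        out, shifts = normalize_run(table, method="median")
        pd.testing.assert_series_equal(out["log2_ratio"], table["log2_ratio"])
        assert shifts.iloc[0] == 0.0

    def test_none_is_identity(self):
        table = peptide_table([0.3, 0.9, -0.4])
        out, _ = normalize_run(table, method="none")
        pd.testing.assert_frame_equal(out, table)

    def test_per_channel_pair_centering(self):
        t1 = peptide_table(np.arange(11) * 0.1, sample="AML01")
        t2 = peptide_table(np.arange(11) * 0.1 + 2.0, sample="AML02")
        out, _ = normalize_run(pd.concat([t1, t2]), method="median")
        for _, grp in out.groupby("sample_id"):
            assert np.median(grp["log2_ratio"]) == pytest.approx(0.0)

    def test_empty_run_and_nonfinite_handling(self):
        with pytest.raises(QuantError):
            normalize_run(peptide_table([]))
        table = peptide_table([0.1, np.nan, 0.3, np.inf, -0.1])
        out, _ = normalize_run(table)
        assert len(out) == 3


class TestControlNull:
    def test_limits_match_sort_oracle(self, rng):
        values = np.tile([-1.0, -0.5, 0.0, 0.5, 1.0], 40)
        rng.shuffle(values)
        null = build_control_null(values, confidence=0.90)
        assert null.lower == pytest.approx(sort_quantile_oracle(values, 0.05))
        assert null.upper == pytest.approx(sort_quantile_oracle(values, 0.95))

    def test_symmetric_null_gives_symmetric_limits(self, rng):
        values = rng.normal(0, 0.5, 5000)
        values = np.concatenate([values, -values])  # exactly symmetric
        null = build_control_null(values)
        assert null.lower == pytest.approx(-null.upper, abs=1e-9)

    def test_gaussian_upper_limit_near_closed_form(self, rng):
        sd = 0.4
        null = build_control_null(rng.normal(0, sd, 10_000), confidence=0.90)
        assert null.upper == pytest.approx(1.645 * sd, abs=0.03)
        assert null.lower == pytest.approx(-1.645 * sd, abs=0.03)

    def test_too_few_ratios_instructs_pooling(self):
        with pytest.raises(InsufficientNullError, match="pool"):
            build_control_null(np.zeros(10), min_null=50)


class TestAggregateProtein:
    @pytest.mark.parametrize("estimator,expected", [("median", 1.2),
                                                    ("mean", 2.4)])
    def test_hand_computed_rollup(self, estimator, expected):
        out = aggregate_protein(peptide_table([1.0, 1.2, 5.0]),
                                estimator=estimator)
        assert len(out) == 1
        assert out["log2_ratio"].iloc[0] == pytest.approx(expected)
        assert out["n_peptides"].iloc[0] == 3

    def test_single_peptide_identity(self):
        out = aggregate_protein(peptide_table([0.42]))
        assert out["log2_ratio"].iloc[0] == pytest.approx(0.42)

    def test_min_peptides_drops_protein(self):
        out = aggregate_protein(peptide_table([0.42]), min_peptides=2)
        assert out.empty

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=9))
    def test_median_rollup_matches_sorting_oracle(self, ratios):
        """Median rollup equals the explicit sort-based median definition."""
        out = aggregate_protein(peptide_table(ratios), estimator="median")
        xs = sorted(ratios)
        n = len(xs)
        oracle = xs[n // 2] if n % 2 else 0.5 * (xs[n // 2 - 1] + xs[n // 2])
        assert out["log2_ratio"].iloc[0] == pytest.approx(oracle)


class TestCallSignificance:
    def null(self, lower=-0.5, upper=0.5, run="run1"):
        # 21 sorted values: the 5%/95% interpolated quantiles land exactly on
        # index 1 and 19, i.e. on (lower, upper)
        ratios = np.array([lower - 0.1, lower] + [0.0] * 17 +
                          [upper, upper + 0.1])
        n = ControlNull(run_id=run, null_ratios=ratios, confidence=0.90)
        assert (n.lower, n.upper) == (lower, upper)
        return n

    def comparisons(self, ratios):
        return aggregate_protein(
            pd.concat([peptide_table([r], sample=f"AML{i:02d}")
                       for i, r in enumerate(ratios)])
        )

    def test_center_and_boundary_not_significant(self):
        out = call_significance(self.comparisons([0.0, 0.5, -0.5]), self.null())
        assert not out["significant"].any()
        assert (out["direction"] == 0).all()

    def test_outside_limits_called_with_direction(self):
        out = call_significance(self.comparisons([0.51, -0.7]), self.null())
        assert out["significant"].all()
        assert list(out["direction"]) == [1, -1]

    def test_run_mismatch_rejected(self):
        with pytest.raises(QuantError):
            call_significance(self.comparisons([0.0]), self.null(run="run9"))

    def test_null_call_rate_matches_one_minus_confidence(self, rng):
        """Operationally, 90% confidence limits flag ~10% of held-out null
        ratios (Monte-Carlo binomial check)."""
        null = build_control_null(rng.normal(0, 0.3, 20_000), confidence=0.90)
        held_out = self.comparisons(rng.normal(0, 0.3, 4000))
        rate = call_significance(held_out, ControlNull(
            run_id="run1", null_ratios=null.null_ratios))["significant"].mean()
        assert rate == pytest.approx(0.10, abs=0.02)

    def test_widening_confidence_never_adds_calls(self, rng):
        ratios = rng.normal(0, 0.3, 5000)
        comps = self.comparisons(rng.normal(0, 0.3, 500))
        n_prev = np.inf
        for conf in (0.80, 0.90, 0.95, 0.99):
            null = build_control_null(ratios, confidence=conf, run_id="run1")
            n_sig = call_significance(comps, null)["significant"].sum()
            assert n_sig <= n_prev
            n_prev = n_sig


class TestSignedFold:
    @pytest.mark.parametrize("log2,expected", [
        (1.0, 2.0), (-1.0, -2.0), (0.0, 1.0), (2.4594, 5.5)])
    def test_known_values(self, log2, expected):
        assert signed_fold(log2) == pytest.approx(expected, abs=0.01)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-10, 10, allow_nan=False))
    def test_magnitude_at_least_one_and_invertible(self, r):
        f = signed_fold(r)
        assert abs(f) >= 1.0
        assert log2_from_signed_fold(f) == pytest.approx(r, abs=1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(QuantError):
            signed_fold(np.nan)
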