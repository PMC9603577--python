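"""Confusion counts, benchmark metrics, and the combination sweep."""

import math

import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from satpred import (
    ConfusionCounts,
    confusion,
    count_mcc_above,
    derive_confusion,
    metrics,
    sweep_combinations,
)
from satpred.benchmark_data import PUBLISHED_MARGINALS, published_benchmark
from satpred.errors import ValidationError
from satpred.performance import UNDEFINED_MARK
from satpred.tool_io import TOOLS

counts_st = st.integers(0, 200)


class TestMetrics:
    def test_best_combination_metrics(self):
        m = metrics(ConfusionCounts(tp=33, tn=2, fp=1, fn=0))
        assert m.accuracy_pct == 97.2
        assert m.sensitivity_pct == 100.0
        assert m.specificity_pct == 66.7
        assert m.mcc_3dp == 0.804

    def test_negative_mcc_single_misclassification(self):
        # one benign miscall out of 3 drives MCC below zero at 97% sensitivity
        m = metrics(ConfusionCounts(tp=32, tn=0, fp=3, fn=1))
        assert m.mcc_3dp == -0.051

    def test_balanced_three_quarters_correct_gives_half(self):
        assert metrics(ConfusionCounts(75, 75, 25, 25)).mcc == pytest.approx(0.5)

    def test_zero_marginal_is_undefined_not_zero(self):
        m = metrics(ConfusionCounts(tp=33, tn=0, fp=3, fn=0))
        assert m.mcc is None
        assert m.mcc_text == UNDEFINED_MARK
        assert m.specificity == 0.0

    def test_empty_confusion_rejected(self):
        with pytest.raises(ValidationError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    @given(tp=counts_st, tn=counts_st, fp=counts_st, fn=counts_st)
    def test_class_swap_symmetry_and_range(self, tp, tn, fp, fn):
        c = ConfusionCounts(tp, tn, fp, fn)
        if c.total == 0:
            return
        m = metrics(c)
        m_swapped = metrics(c.swapped())
        if m.mcc is None:
            assert m_swapped.mcc is None
        else:
            assert m_swapped.mcc == pytest.approx(m.mcc)
            assert -1.0 <= m.mcc <= 1.0
            if fp == fn == 0 and tp > 0 and tn > 0:
                assert m.mcc == pytest.approx(1.0)
            if tp == tn == 0 and fp > 0 and fn > 0:
                assert m.mcc == pytest.approx(-1.0)

    @given(tp=counts_st, tn=counts_st, fp=counts_st, fn=counts_st)
    def test_accuracy_identity(self, tp, tn, fp, fn):
        c = ConfusionCounts(tp, tn, fp, fn)
        m = metrics(c) if c.total else None
        if m is None or m.sensitivity is None or m.specificity is None:
            return
        recombined = (
            m.sensitivity * c.n_pathogenic + m.specificity * c.n_benign
        ) / c.total
        assert m.accuracy == pytest.approx(recombined)


class TestConfusion:
    def test_degenerate_and_perfect_predictors(self, reference_33_3):
        notations = [v.substitution.notation for v in reference_33_3]
        all_path = {n: "pathogenic" for n in notations}
        assert confusion(all_path, reference_33_3) == ConfusionCounts(33, 0, 3, 0)
        perfect = {
            v.substitution.notation: v.label for v in reference_33_3
        }
        assert confusion(perfect, reference_33_3) == ConfusionCounts(33, 3, 0, 0)

    def test_missing_prediction_listed(self, reference_33_3):
        preds = {
            v.substitution.notation: "pathogenic" for v in reference_33_3[:-1]
        }
        missing = reference_33_3[-1].substitution.notation
        with pytest.raises(ValidationError, match=missing):
            confusion(preds, reference_33_3)

    @settings(suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(data=st.data())
    def test_counts_match_brute_force(self, data, reference_33_3):
        preds = {
            v.substitution.notation: data.draw(
                st.sampled_from(["pathogenic", "benign"])
            )
            for v in reference_33_3
        }
        c = confusion(preds, reference_33_3)
        pairs = [(preds[v.substitution.notation], v.label) for v in reference_33_3]
        assert c.tp == pairs.count(("pathogenic", "pathogenic"))
        assert c.tn == pairs.count(("benign", "benign"))
        assert c.fp == pairs.count(("pathogenic", "benign"))
        assert c.fn == pairs.count(("benign", "pathogenic"))
        assert c.total == 36


class TestDeriveConfusion:
    @pytest.mark.parametrize(
        "sens, spec, expected",
        [
            (100.0, 66.7, ConfusionCounts(33, 2, 1, 0)),
            (97.0, 0.0, ConfusionCounts(32, 0, 3, 1)),
            (100.0, 100.0, ConfusionCounts(33, 3, 0, 0)),
            (100.0, 33.3, ConfusionCounts(33, 1, 2, 0)),
        ],
    )
    def test_nearest_integer_reconstruction(self, sens, spec, expected):
        assert derive_confusion(33, 3, sens, spec) == expected

    def test_round_trip_on_all_published_rows(self):
        for _, _, sens, spec in PUBLISHED_MARGINALS:
            c = derive_confusion(33, 3, sens, spec)
            m = metrics(c)
            assert m.sensitivity_pct == pytest.approx(round(sens, 1), abs=0.05)
            assert m.specificity_pct == pytest.approx(round(spec, 1), abs=0.05)

    def test_published_accuracy_reproduced_from_counts(self):
        bench = published_benchmark()
        assert (bench["accuracy"] == bench["published_accuracy"]).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            derive_confusion(0, 3, 100, 100)
        with pytest.raises(ValidationError):
            derive_confusion(33, 3, 101, 0)


class TestSweep:
    @staticmethod
    def calls_frame(reference, per_tool):
        rows = []
        for tool in TOOLS:
            for v in reference:
                rows.append(
                    {
                        "notation": v.substitution.notation,
                        "tool": tool,
                        "call": per_tool[tool](v),
                    }
                )
        return pd.DataFrame(rows)

    def test_fifteen_rows_all_perfect(self, reference_33_3):
        calls = self.calls_frame(
            reference_33_3, {t: (lambda v: v.label) for t in TOOLS}
        )
        bench = sweep_combinations(calls, reference_33_3)
        assert len(bench) == 15
        assert bench["n_tools"].tolist() == [1] * 4 + [2] * 6 + [3] * 4 + [4]
        assert (bench["mcc"] == 1.0).all()
        assert count_mcc_above(bench) == 15

    def test_rows_match_independent_per_subset_oracle(self, reference_33_3):
        import itertools
        import numpy as np

        rng = np.random.default_rng(5)
        fixed = {
            t: {
                v.substitution.notation: rng.choice(["pathogenic", "benign"], p=[0.8, 0.2])
                for v in reference_33_3
            }
            for t in TOOLS
        }
        calls = self.calls_frame(reference_33_3, {t: (lambda v, t=t: fixed[t][v.substitution.notation]) for t in TOOLS})
        bench = sweep_combinations(calls, reference_33_3)
        from satpred import combine

        for row in bench.itertuples():
            subset = row.tools.split(",")
            preds = {}
            for v in reference_33_3:
                n = v.substitution.notation
                votes = [fixed[t][n] for t in subset]
                preds[n] = votes[0] if len(votes) == 1 else combine(votes)
            c = confusion(preds, reference_33_3)
            assert (row.tp, row.tn, row.fp, row.fn) == (c.tp, c.tn, c.fp, c.fn)
            m = metrics(c)
            assert row.mcc_text == m.mcc_text

    def test_row_count_scales_as_subsets(self, reference_33_3):
        calls = self.calls_frame(
            reference_33_3, {t: (lambda v: v.label) for t in TOOLS}
        )
        for k in (2, 3):
            bench = sweep_combinations(calls, reference_33_3, tools=TOOLS[:k])
            assert len(bench) == 2**k - 1

    def test_missing_calls_rejected(self, reference_33_3):
        calls = self.calls_frame(
            reference_33_3, {t: (lambda v: v.label) for t in TOOLS}
        )
        with pytest.raises(ValidationError):
            sweep_combinations(calls[calls["tool"] != "sift"], reference_33_3)
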