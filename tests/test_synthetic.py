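"""Synthetic score tables and exact-confusion reference sets."""

import math

import numpy as np
import pandas as pd
import pytest

from satpred import (
    SyntheticConfig,
    calibrate_weights,
    confusion,
    metrics,
    simulate_reference,
    simulate_scores,
    synthetic_sequence,
    tabulate_categories,
    write_score_table,
)
from satpred.errors import CalibrationError, ConfigurationError, ValidationError
from satpred.performance import ConfusionCounts
from satpred.synthetic import DEFAULT_TARGET_RATES


class TestCalibration:
    def test_weights_hit_target_exactly_in_expectation(self):
        p_a, p_b, pi = 0.98, 0.03, 0.94
        for target in (0.958, 0.826, 0.5, 0.1):
            w_p, w_b = calibrate_weights(p_a, p_b, pi, target)
            f = lambda w: p_b + w * (p_a - p_b)
            rate = pi * f(w_p) + (1 - pi) * f(w_b)
            assert rate == pytest.approx(target, abs=1e-12)
            assert 0.0 <= w_b <= w_p <= 1.0

    def test_unreachable_target_raises(self):
        with pytest.raises(CalibrationError):
            calibrate_weights(0.9, 0.1, 0.94, 0.95)
        with pytest.raises(CalibrationError):
            calibrate_weights(0.9, 0.1, 0.94, 0.05)
        with pytest.raises(CalibrationError):
            calibrate_weights(0.2, 0.5, 0.94, 0.3)  # components inverted


class TestSimulateScores:
    def test_empirical_rates_within_three_binomial_se(self):
        cfg = SyntheticConfig(seed=11)
        scores, _ = simulate_scores(cfg)
        tab = tabulate_categories(scores).set_index("tool")
        n = 5700
        for tool, target in DEFAULT_TARGET_RATES.items():
            p = target / 100.0
            se_pct = 100.0 * math.sqrt(p * (1 - p) / n)
            observed = tab.loc[tool, "pathogenic_n"] / n * 100.0
            assert abs(observed - target) <= 3 * se_pct, tool

    def test_deterministic_and_byte_identical(self, tmp_path):
        cfg = SyntheticConfig(seed=42, length=30)
        s1, l1 = simulate_scores(cfg)
        s2, l2 = simulate_scores(SyntheticConfig(seed=42, length=30))
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(l1, l2)
        p1 = write_score_table(s1, tmp_path / "a.tsv")
        p2 = write_score_table(s2, tmp_path / "b.tsv")
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seeds_differ(self):
        s1, _ = simulate_scores(SyntheticConfig(seed=1, length=20))
        s2, _ = simulate_scores(SyntheticConfig(seed=2, length=20))
        assert not s1["score"].equals(s2["score"])

    def test_all_benign_degenerate_case(self):
        cfg = SyntheticConfig(
            seed=3,
            length=20,
            latent_pathogenic_rate=0.0,
            target_rates={"sift": 3.3},
        )
        scores, latent = simulate_scores(cfg)
        assert (latent["latent_label"] == "benign").all()
        tab = tabulate_categories(scores).set_index("tool")
        # benign component of SIFT places ~3% mass below the cutoff
        assert tab.loc["sift", "pathogenic_pct"] < 10.0

    def test_table_is_complete_saturation(self):
        cfg = SyntheticConfig(seed=5, length=25)
        scores, _ = simulate_scores(cfg)
        assert len(scores) == 19 * 25 * len(DEFAULT_TARGET_RATES)
        per_tool = scores.groupby("tool").size()
        assert (per_tool == 19 * 25).all()

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text(
            "seed: 9\nlength: 40\nlatent_pathogenic_rate: 0.9\n"
            "target_rates:\n  provean: 80.0\n"
        )
        cfg = SyntheticConfig.from_yaml(p)
        assert (cfg.seed, cfg.length) == (9, 40)
        assert cfg.target_rates == {"provean": 80.0}
        bad = tmp_path / "bad.yaml"
        bad.write_text("lenght: 40\n")
        with pytest.raises(ConfigurationError):
            SyntheticConfig.from_yaml(bad)


class TestSimulateReference:
    def test_confusions_match_spec_exactly(self):
        cfg = SyntheticConfig(seed=6)
        ref, calls, expected = simulate_reference(cfg)
        labels = [v.label for v in ref]
        assert labels.count("pathogenic") == 33 and labels.count("benign") == 3
        for tool, exp in expected.items():
            part = calls[calls["tool"] == tool]
            got = confusion(dict(zip(part["notation"], part["call"])), ref)
            assert got == exp

    @pytest.mark.parametrize("overlap", ["maximal", "disjoint", "random"])
    def test_exactness_for_random_feasible_specs(self, overlap):
        rng = np.random.default_rng(13)
        for trial in range(5):
            n_p, n_b = int(rng.integers(5, 40)), int(rng.integers(2, 10))
            spec = {}
            for tool in ("humdiv", "provean"):
                tp = int(rng.integers(0, n_p + 1))
                tn = int(rng.integers(0, n_b + 1))
                spec[tool] = (100.0 * tp / n_p, 100.0 * tn / n_b)
            cfg = SyntheticConfig(
                seed=trial,
                n_pathogenic=n_p,
                n_benign=n_b,
                reference_spec=spec,
                overlap=overlap,
            )
            ref, calls, expected = simulate_reference(cfg)
            for tool, exp in expected.items():
                part = calls[calls["tool"] == tool]
                got = confusion(dict(zip(part["notation"], part["call"])), ref)
                assert got == exp

    def test_panel_overlap_reproduces_best_consensus(self):
        # all three panel tools at sensitivity 100 / specificity 66.7 with
        # maximally overlapping errors: the majority consensus then shows
        # exactly one false positive, i.e. counts (33, 2, 1, 0)
        from satpred import combine

        spec = {t: (100.0, 66.7) for t in ("humdiv", "humvar", "provean")}
        cfg = SyntheticConfig(seed=8, reference_spec=spec, overlap="maximal")
        ref, calls, _ = simulate_reference(cfg)
        per_tool = {
            t: dict(
                zip(
                    calls[calls["tool"] == t]["notation"],
                    calls[calls["tool"] == t]["call"],
                )
            )
            for t in spec
        }
        consensus = {
            v.substitution.notation: combine(
                [per_tool[t][v.substitution.notation] for t in spec]
            )
            for v in ref
        }
        c = confusion(consensus, ref)
        assert c == ConfusionCounts(33, 2, 1, 0)
        m = metrics(c)
        assert (m.accuracy_pct, m.mcc_3dp) == (97.2, 0.804)

    def test_perfect_tools_make_perfect_sweep(self):
        from satpred import sweep_combinations

        spec = {t: (100.0, 100.0) for t in ("humdiv", "humvar", "provean", "sift")}
        cfg = SyntheticConfig(seed=10, reference_spec=spec)
        ref, calls, _ = simulate_reference(cfg)
        bench = sweep_combinations(calls, ref)
        assert (bench["mcc"] == 1.0).all()

    def test_reference_determinism(self):
        r1, c1, _ = simulate_reference(SyntheticConfig(seed=21))
        r2, c2, _ = simulate_reference(SyntheticConfig(seed=21))
        assert [v.substitution for v in r1] == [v.substitution for v in r2]
        pd.testing.assert_frame_equal(c1, c2)

    def test_reference_too_large(self):
        cfg = SyntheticConfig(seed=1, length=1, n_pathogenic=30, n_benign=5)
        with pytest.raises(ValidationError):
            simulate_reference(cfg)


def test_synthetic_sequence_deterministic():
    a = synthetic_sequence(50, 7)
    b = synthetic_sequence(50, 7)
    c = synthetic_sequence(50, 8)
    assert a.residues == b.residues
    assert a.residues != c.residues
    assert len(a) == 50
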