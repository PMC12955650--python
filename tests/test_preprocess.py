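"""Confidence discretization, RT binning, table building, padding, and
the below-chance screen."""

import numpy as np
import pandas as pd
import pytest

import uvsdt as u
from uvsdt.preprocess import exclude_below_chance

from conftest import random_table


def make_trials(stim, resp, rt=None, conf=None, subject="s0"):
    n = len(stim)
    return pd.DataFrame(
        {
            "subject": subject,
            "stimulus": stim,
            "response": resp,
            "rt": rt if rt is not None else np.ones(n),
            "confidence": conf if conf is not None else np.ones(n),
        }
    )


class TestDiscretizeConfidence:
    def test_exact_tertiles(self):
        t = make_trials([0] * 6, [0] * 6, conf=[10, 20, 30, 40, 50, 60])
        out = u.discretize_confidence(t, 3)
        assert out["confidence_level"].tolist() == [1, 1, 2, 2, 3, 3]

    def test_all_equal_confidence_errors_naming_subject(self):
        t = make_trials([0] * 6, [0] * 6, conf=[5] * 6, subject="bad")
        with pytest.raises(ValueError, match="bad"):
            u.discretize_confidence(t, 3)

    def test_uniform_sample_balanced_levels(self, rng):
        n = 300
        t = make_trials([0] * n, [0] * n, conf=rng.uniform(0, 100, n))
        out = u.discretize_confidence(t, 3)
        counts = out["confidence_level"].value_counts()
        assert all(abs(counts[lev] - n / 3) <= 1 for lev in (1, 2, 3))

    def test_per_subject_cutpoints(self):
        # same raw value maps to different levels for different subjects
        a = make_trials([0] * 4, [0] * 4, conf=[1, 2, 3, 4], subject="a")
        b = make_trials([0] * 4, [0] * 4, conf=[3, 4, 5, 6], subject="b")
        out = u.discretize_confidence(pd.concat([a, b], ignore_index=True), 2)
        lev = out.set_index(["subject", "confidence"])["confidence_level"]
        assert lev[("a", 3)] == 2 and lev[("b", 3)] == 1


class TestBinRT:
    def test_exact_tertiles_fastest_is_strongest(self):
        t = make_trials([0] * 6, [0] * 6, rt=[0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
        out = u.bin_rt(t, 3)
        assert out["rt_strength"].tolist() == [3, 3, 2, 2, 1, 1]

    def test_fewer_trials_than_bins_errors(self):
        t = make_trials([0, 1], [0, 1], rt=[0.3, 0.4])
        with pytest.raises(ValueError, match="fewer"):
            u.bin_rt(t, 3)

    def test_identical_rts_error_or_fallback(self):
        t = make_trials([0] * 6, [0] * 6, rt=[0.5] * 6)
        with pytest.raises(ValueError, match="identical"):
            u.bin_rt(t, 3)
        out = u.bin_rt(t, 3, on_degenerate="single_level")
        assert (out["rt_strength"] == 1).all()

    def test_exponential_rts_balanced_bins(self, rng):
        n = 400
        t = make_trials([0] * n, [0] * n, rt=rng.exponential(1.0, n))
        out = u.bin_rt(t, 4)
        counts = out["rt_strength"].value_counts()
        assert all(abs(counts[s] - n / 4) <= 1 for s in (1, 2, 3, 4))

    def test_within_response_scheme_bins_each_response(self, rng):
        n = 200
        t = make_trials(
            [0, 1] * (n // 2),
            [0, 1] * (n // 2),
            rt=rng.exponential(1.0, n),
        )
        out = u.bin_rt(t, 2, scheme="within_response")
        for _, grp in out.groupby("response"):
            counts = grp["rt_strength"].value_counts()
            assert abs(counts[1] - counts[2]) <= 1

    def test_pooled_binning_matches_evidence_distance_oracle(self):
        """With noise-free RTs, quantile-binning RT equals quantile-binning
        the evidence distance |x - c0| directly (reversed order)."""
        cfg = u.SimConfig(
            mu=1.0, sigma=1.3, n_levels=3, n_trials=300,
            rt_model=u.RTModel(tau=0.0), seed=11,
        )
        trials = u.simulate_observer(cfg)
        out = u.bin_rt(trials, 3)
        dist = np.abs(trials["evidence"].to_numpy() - cfg.c0)
        cuts = np.quantile(dist, [1 / 3, 2 / 3])
        oracle = 1 + np.searchsorted(cuts, dist, side="left")
        assert np.array_equal(out["rt_strength"].to_numpy(), oracle)


class TestBuildTable:
    def test_direct_tabulation(self):
        t = make_trials(
            [1, 1, 0, 0], [1, 0, 1, 0], conf=[3, 1, 1, 3]
        )
        tab = u.build_table(t, 3, evidence="confidence")
        np.testing.assert_array_equal(tab.freq[1], [1, 0, 0, 1, 0, 0])
        np.testing.assert_array_equal(tab.freq[0], [0, 0, 1, 0, 0, 1])

    def test_total_is_trial_count(self, rng):
        n = 50
        t = make_trials(
            rng.integers(0, 2, n), rng.integers(0, 2, n),
            conf=rng.integers(1, 4, n),
        )
        assert u.build_table(t, 3).total == n

    def test_empty_stimulus_class_errors(self):
        t = make_trials([1, 1], [1, 0], conf=[1, 1])
        with pytest.raises(ValueError, match="stimulus class"):
            u.build_table(t, 2)

    def test_trial_order_irrelevant(self, rng):
        n = 60
        t = make_trials(
            rng.integers(0, 2, n), rng.integers(0, 2, n),
            conf=rng.integers(1, 4, n),
        )
        shuffled = t.sample(frac=1, random_state=1).reset_index(drop=True)
        np.testing.assert_array_equal(
            u.build_table(t, 3).freq, u.build_table(shuffled, 3).freq
        )

    def test_simulated_observer_rates_match_model(self):
        cfg = u.SimConfig(
            mu=1.5, sigma=1.5, n_levels=2, confidence_criteria=[-1, 0, 1],
            n_trials=10_000, seed=4,
        )
        tab = u.build_table(u.simulate_observer(cfg), 2)
        fa, hit = tab.cumulative_rates()
        curve = u.model_roc(u.UVSDTParams(1.5, 1.5, [-1, 0, 1]))
        np.testing.assert_allclose(
            np.column_stack([fa, hit]), curve.criteria_points, atol=0.02
        )


class TestPadTable:
    def test_adds_one_over_n(self):
        freq = np.array([[13, 12, 13, 12], [12, 13, 12, 13]], dtype=float)  # N=100
        tab = u.RatingTable(2, freq)
        padded = u.pad_table(tab)
        np.testing.assert_allclose(padded.freq, tab.freq + 0.01)
        assert padded.padded

    def test_zero_cell_becomes_positive(self):
        tab = u.RatingTable(2, [[10, 0, 0, 0], [0, 0, 0, 10]])
        padded = u.pad_table(tab)
        assert np.all(padded.freq > 0)
        assert padded.freq[0, 1] == pytest.approx(1 / 20)

    def test_double_padding_errors(self):
        tab = u.pad_table(u.RatingTable(2, np.ones((2, 4))))
        with pytest.raises(ValueError, match="already padded"):
            u.pad_table(tab)

    def test_padding_preserves_rate_ordering(self, rng):
        for _ in range(30):
            tab = random_table(rng, n_levels=3)
            fa0, hit0 = tab.cumulative_rates()
            fa1, hit1 = u.pad_table(tab).cumulative_rates()
            assert np.all(np.diff(fa1) >= 0) and np.all(np.diff(hit1) >= 0)
            # ordering of the unpadded rates is preserved
            assert np.array_equal(np.argsort(fa0, kind="stable"),
                                  np.argsort(fa1, kind="stable"))


class TestExcludeBelowChance:
    @staticmethod
    def table_with_rates(hit, fa, n=100):
        n2 = n // 2
        freq = np.array(
            [
                [fa * n2 / 2, fa * n2 / 2, (1 - fa) * n2 / 2, (1 - fa) * n2 / 2],
                [hit * n2 / 2, hit * n2 / 2, (1 - hit) * n2 / 2, (1 - hit) * n2 / 2],
            ]
        )
        return u.RatingTable(2, freq, padded=True)

    def test_screen_flags(self):
        tables = {
            "good": self.table_with_rates(0.7, 0.3),
            "bad": self.table_with_rates(0.3, 0.7),
            "chance": self.table_with_rates(0.5, 0.5),
        }
        report = exclude_below_chance(tables)
        assert report.flags["good"] == "retained"
        assert report.flags["bad"] == "below_chance"
        assert report.flags["chance"] == "below_chance"  # boundary excluded
        assert report.n_input_subjects == 3
        assert report.n_below_chance_excluded == 2
        assert report.n_final == 1

    def test_boundary_convention_configurable(self):
        tables = {"chance": self.table_with_rates(0.5, 0.5)}
        report = exclude_below_chance(tables, boundary_excludes=False)
        assert report.flags["chance"] == "retained"
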