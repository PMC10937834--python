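"""Rhythm census statistics: χ² homogeneity, overlaps, KS comparisons,
acrophase histograms and session effects on rhythm parameters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhythmix.census import (acrophase_chisq, acrophase_histogram,
                             acrophase_session_compare,
                             amplitude_session_anova, classify_peak_window,
                             compare_distributions_ks, overlap_matrices,
                             rhythmic_counts_chisq)
from rhythmix.cosinor import BootstrapSettings


def flags_frame(cols: dict, n: int) -> pd.DataFrame:
    out = pd.DataFrame(False, index=[f"T{i}" for i in range(n)],
                       columns=list(cols))
    for s, idx in cols.items():
        out.loc[[f"T{i}" for i in idx], s] = True
    return out


class TestCountsChisq:
    def test_identical_counts_null(self):
        f = flags_frame({"A": range(10), "B": range(10)}, 100)
        chi2, dof, p = rhythmic_counts_chisq(f)
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_two_by_two_closed_form(self):
        # 50/1000 vs 100/1000 rhythmic; hand computation:
        # expected 75/925 per session, chi2 = 625*(2/75 + 2/925) = 18.018...
        f = flags_frame({"A": range(50), "B": range(100)}, 1000)
        chi2, dof, p = rhythmic_counts_chisq(f)
        hand = 625.0 * (2.0 / 75.0 + 2.0 / 925.0)
        assert chi2 == pytest.approx(hand, rel=1e-12)
        assert dof == 1

    def test_null_simulation_type_one_error(self):
        rng = np.random.default_rng(0)
        n_sim, rej = 300, 0
        for _ in range(n_sim):
            f = pd.DataFrame(rng.random((400, 3)) < 0.2,
                             columns=["A", "B", "C"])
            _, _, p = rhythmic_counts_chisq(f)
            rej += p < 0.05
        rate = rej / n_sim
        assert rate == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / n_sim) + 0.01)


class TestOverlaps:
    def test_identical_columns_full_overlap(self):
        f = flags_frame({"A": range(20), "B": range(20)}, 50)
        c = overlap_matrices(f)
        assert np.allclose(c.jaccard, 100.0)
        assert np.allclose(c.conditional, 100.0)
        assert len(c.always_rhythmic) == 20

    def test_disjoint_sets_zero_offdiagonal(self):
        f = flags_frame({"A": range(10), "B": range(10, 20)}, 50)
        c = overlap_matrices(f)
        assert c.jaccard.iloc[0, 1] == 0.0
        assert c.jaccard.iloc[0, 0] == 100.0
        assert c.always_rhythmic == []

    def test_matches_set_operation_loop(self):
        rng = np.random.default_rng(1)
        f = pd.DataFrame(rng.random((80, 4)) < 0.3, columns=list("ABCD"),
                         index=[f"T{i}" for i in range(80)])
        c = overlap_matrices(f)
        sets = {s: set(f.index[f[s]]) for s in f.columns}
        for i, a in enumerate(f.columns):
            for j, b in enumerate(f.columns):
                inter = len(sets[a] & sets[b])
                union = len(sets[a] | sets[b])
                assert c.jaccard.iloc[i, j] == pytest.approx(
                    100 * inter / union if union else 0.0)
                assert c.conditional.iloc[i, j] == pytest.approx(
                    100 * inter / len(sets[b]) if sets[b] else 0.0)

    def test_jaccard_bounded_by_conditional(self):
        rng = np.random.default_rng(2)
        f = pd.DataFrame(rng.random((60, 3)) < 0.4, columns=list("ABC"))
        c = overlap_matrices(f)
        for i in range(3):
            for j in range(3):
                assert c.jaccard.iloc[i, j] <= min(
                    c.conditional.iloc[i, j], c.conditional.iloc[j, i]) + 1e-9


class TestKs:
    def test_identical_samples_null(self):
        v = {"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0]}
        out = compare_distributions_ks(v)
        assert out["D"].iloc[0] == 0.0 and out["p"].iloc[0] == pytest.approx(1.0)

    def test_disjoint_supports_give_D_one(self):
        out = compare_distributions_ks({"A": [0.1, 0.2, 0.3], "B": [0.4, 0.5, 0.6]})
        assert out["D"].iloc[0] == pytest.approx(1.0)

    def test_statistic_equals_bruteforce_ecdf_gap(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=40), rng.normal(0.5, 1.2, size=60)
        out = compare_distributions_ks({"A": a, "B": b})
        grid = np.sort(np.concatenate([a, b]))
        gap = max(abs((a <= x).mean() - (b <= x).mean()) for x in grid)
        assert out["D"].iloc[0] == pytest.approx(gap, abs=1e-12)

    def test_symmetric_in_session_order(self):
        rng = np.random.default_rng(4)
        v = {"A": rng.normal(size=30), "B": rng.normal(size=30)}
        d1 = compare_distributions_ks(v)["D"].iloc[0]
        d2 = compare_distributions_ks({"B": v["B"], "A": v["A"]})["D"].iloc[0]
        assert d1 == pytest.approx(d2)


class TestHistogram:
    def test_single_value_lands_in_floor_bin(self):
        h = acrophase_histogram([0.5])
        assert h[0] == 1 and h.sum() == 1

    def test_boundary_goes_to_later_bin(self):
        h = acrophase_histogram([1.0])
        assert h[1] == 1

    def test_clock_offset_shift(self):
        h = acrophase_histogram([2.0], clock_offset=8.0)
        assert h[10] == 1

    def test_uniform_simulation_multinomial(self):
        rng = np.random.default_rng(5)
        h = acrophase_histogram(rng.uniform(0, 24, 24000))
        expect = 1000.0
        sd = np.sqrt(24000 * (1 / 24) * (23 / 24))
        assert (np.abs(h - expect) < 5 * sd).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            acrophase_histogram([24.0])


class TestAcrophaseChisq:
    def test_identical_histograms_null(self):
        h = np.array([5, 3, 0, 2] * 6)
        chi2, dof, p = acrophase_chisq(h, h)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_pooled_table_matches_closed_form(self):
        # effectively a 2x2 after pooling zero bins
        a = np.zeros(24, dtype=int); a[0], a[12] = 30, 10
        b = np.zeros(24, dtype=int); b[0], b[12] = 10, 30
        chi2, dof, p = acrophase_chisq(a, b)
        from scipy.stats import chi2_contingency
        ref = chi2_contingency(np.array([[30, 10], [10, 30]]),
                               correction=False)[0]
        assert chi2 == pytest.approx(ref, rel=1e-12)
        assert dof == 1

    def test_empty_histograms_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            acrophase_chisq(np.zeros(24), np.zeros(24))

    def test_same_distribution_type_one_error(self):
        rng = np.random.default_rng(6)
        n_sim, rej = 300, 0
        for _ in range(n_sim):
            a = acrophase_histogram(rng.uniform(0, 24, 300))
            b = acrophase_histogram(rng.uniform(0, 24, 300))
            _, _, p = acrophase_chisq(a, b)
            rej += p < 0.05
        assert rej / n_sim == pytest.approx(
            0.05, abs=3 * np.sqrt(0.05 * 0.95 / n_sim) + 0.015)


class TestAmplitudeAnova:
    def frame(self, fn, P=12, S=4):
        rows = [{"participant": f"P{i}", "session": f"S{j}", "amp_i": fn(i, j)}
                for i in range(P) for j in range(S)]
        return pd.DataFrame(rows)

    def test_identical_amplitudes_null(self):
        res = amplitude_session_anova(self.frame(lambda i, j: 1.0))
        assert res.anova_table["F"].iloc[0] == pytest.approx(0.0, abs=1e-8)

    def test_doubled_session_detected(self):
        rng = np.random.default_rng(7)
        res = amplitude_session_anova(self.frame(
            lambda i, j: (2.0 if j == 1 else 1.0) + rng.normal(0, 0.05)))
        assert res.anova_table["p"].iloc[0] < 1e-3


class TestAcrophaseCompare:
    def frame(self, fn, P=10, S=3):
        rows = [{"participant": f"P{i}", "session": f"S{j}",
                 "acrophase_i": fn(i, j) % 24}
                for i in range(P) for j in range(S)]
        return pd.DataFrame(rows)

    def test_equal_acrophases_no_differences(self):
        means, pairs = acrophase_session_compare(
            self.frame(lambda i, j: 5.0), BootstrapSettings(100, seed=1))
        assert np.allclose(means["circ_mean"], 5.0)
        assert not pairs["different"].any()

    def test_separated_sessions_flagged(self):
        rng = np.random.default_rng(8)
        means, pairs = acrophase_session_compare(
            self.frame(lambda i, j: (2.0 if j == 0 else 14.0)
                       + rng.normal(0, 0.3)),
            BootstrapSettings(200, seed=2))
        row = pairs[(pairs["session_a"] == "S0") & (pairs["session_b"] == "S1")]
        assert row["different"].iloc[0]

    def test_wraparound_across_midnight(self):
        rng = np.random.default_rng(9)
        means, pairs = acrophase_session_compare(
            self.frame(lambda i, j: (23.5 if j == 0 else 0.5)
                       + rng.normal(0, 0.2), S=2),
            BootstrapSettings(200, seed=3))
        d = pairs["circ_distance"].iloc[0]
        assert d == pytest.approx(1.0, abs=0.3)   # 1 h apart, not 23 h


class TestPeakWindows:
    @pytest.mark.parametrize("hour,label", [
        (12.0, "day"), (23.0, "night"), (7.0, "morning"), (18.0, "evening"),
        (11.0, "day"), (21.0, "night"), (6.99, "night"), (10.99, "morning"),
        (17.99, "day"), (20.99, "evening"), (0.0, "night"),
    ])
    def test_window_assignment(self, hour, label):
        assert classify_peak_window(hour) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_peak_window(24.0)
        with pytest.raises(ValueError):
            classify_peak_window(-0.1)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=23.999999))
    def test_windows_partition_the_day(self, hour):
        assert classify_peak_window(hour) in {"day", "night", "morning", "evening"}
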