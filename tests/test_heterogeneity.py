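"""Reclassification tables, discordance, test battery and correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pdl1het.heterogeneity import (
    HeterogeneityError,
    ReclassificationTable,
    compare_groups,
    correlate,
    dunn_posthoc,
    fisher_z_ci,
    inter_tumoral_discordance,
    intra_tumoral_reclassification,
)
from pdl1het.scoring import categorize

from conftest import make_scored_frame


class TestIntraTumoralReclassification:
    def test_identical_pairs_concordant(self):
        frame = make_scored_frame([(10, 10), (0, 0), (25, 25)])
        table, pairs = intra_tumoral_reclassification(frame, "CPS")
        assert table.reclassification_rate == 0.0
        assert table.trace == 3
        assert not any(p.discordant for p in pairs)

    def test_negative_to_low_transition(self):
        frame = make_scored_frame([(0.4, 5)])
        table, pairs = intra_tumoral_reclassification(frame, "CPS")
        assert pairs[0].reference_category == "negative"
        assert pairs[0].comparison_category == "low"
        assert table.counts[0, 1] == 1

    def test_hand_classified_six_pairs(self):
        # (0.5,2) neg->low; (3,3) low->low; (21,18) high->low; (0,0) neg->neg;
        # (2,25) low->high; (19,20) low->high  => 4 of 6 discordant
        vals = [(0.5, 2), (3, 3), (21, 18), (0, 0), (2, 25), (19, 20)]
        frame = make_scored_frame(vals)
        table, pairs = intra_tumoral_reclassification(frame, "CPS")
        assert table.n_pairs == 6
        assert table.reclassification_rate == pytest.approx(4 / 6)
        # exhaustive cross-check against scalar categorize
        expected = np.zeros((3, 3), dtype=int)
        idx = {"negative": 0, "low": 1, "high": 2}
        for r, c in vals:
            expected[idx[categorize(r, "CPS")], idx[categorize(c, "CPS")]] += 1
        assert (table.counts == expected).all()

    def test_lesions_without_two_passing_cores_skipped(self, caplog):
        frame = make_scored_frame([(5, 5), (7, 9)])
        frame.loc[frame["core_id"] == "L1-c2", "qc_pass"] = False
        with caplog.at_level("WARNING"):
            table, _ = intra_tumoral_reclassification(frame, "CPS")
        assert table.n_pairs == 1
        assert "skipped 1" in caplog.text

    def test_reference_is_sample_index_not_row_order(self):
        frame = make_scored_frame([(0.4, 30)]).iloc[::-1].reset_index(drop=True)
        _, pairs = intra_tumoral_reclassification(frame, "CPS")
        assert pairs[0].reference_value == 0.4

    def test_conservation_identity(self, small_cohort):
        from pdl1het.scoring import score_cores

        cores, _ = small_cohort
        scored = score_cores(cores)
        for scheme in ("CPS", "TPS"):
            table, _ = intra_tumoral_reclassification(scored, scheme)
            assert table.counts.sum() == table.n_pairs
            off_diag = table.counts.sum() - table.trace
            assert table.trace + off_diag == table.n_pairs


def _lesion_frame(cps_pairs, type_a="primary", type_b="lymph_node_met"):
    rows = []
    for i, (a, b) in enumerate(cps_pairs):
        for t, v in ((type_a, a), (type_b, b)):
            rows.append(
                {"patient_id": f"P{i}", "lesion_id": f"P{i}-{t}", "lesion_type": t,
                 "cps": float(v), "tps": float(v), "excluded": False}
            )
    return pd.DataFrame(rows)


class TestInterTumoralDiscordance:
    def test_shared_scores_concordant_with_degenerate_wilcoxon(self):
        frame = _lesion_frame([(5, 5), (0, 0), (30, 30)])
        table, _, test = inter_tumoral_discordance(frame, "primary", "lymph_node_met")
        assert table.reclassification_rate == 0.0
        assert test.n == 0
        assert test.p_value == 1.0

    def test_hand_classified_four_patients(self):
        # (5,0.5) low->neg; (30,25) high->high; (0,2) neg->low; (15,18) low->low
        frame = _lesion_frame([(5, 0.5), (30, 25), (0, 2), (15, 18)])
        table, _, _ = inter_tumoral_discordance(frame, "primary", "lymph_node_met")
        assert table.n_pairs == 4
        assert table.reclassification_rate == pytest.approx(0.5)

    def test_swapping_types_transposes_counts(self):
        frame = _lesion_frame([(5, 0.5), (30, 25), (0, 2), (15, 18), (22, 3)])
        t_ab, _, _ = inter_tumoral_discordance(frame, "primary", "lymph_node_met")
        t_ba, _, _ = inter_tumoral_discordance(frame, "lymph_node_met", "primary")
        assert (t_ab.counts == t_ba.counts.T).all()

    def test_multiple_lesions_of_one_type_averaged(self):
        frame = _lesion_frame([(10, 4)])
        extra = frame.iloc[[0]].assign(lesion_id="P0-primary-2", cps=20.0, tps=20.0)
        frame = pd.concat([frame, extra], ignore_index=True)
        _, pairs, _ = inter_tumoral_discordance(frame, "primary", "lymph_node_met")
        assert pairs[0].reference_value == pytest.approx(15.0)

    def test_no_common_patients_is_error(self):
        frame = _lesion_frame([(10, 4)])
        frame = frame[frame["lesion_type"] == "primary"]
        with pytest.raises(HeterogeneityError):
            inter_tumoral_discordance(frame, "primary", "distant_met")

    def test_patient_relabeling_invariance(self):
        frame = _lesion_frame([(5, 0.5), (30, 25), (0, 2)])
        relabeled = frame.assign(patient_id=frame["patient_id"].map(lambda s: "X" + s))
        t1, _, _ = inter_tumoral_discordance(frame, "primary", "lymph_node_met")
        t2, _, _ = inter_tumoral_discordance(relabeled, "primary", "lymph_node_met")
        assert (t1.counts == t2.counts).all()


class TestCompareGroups:
    def test_identical_paired_vectors_give_p_one(self):
        res = compare_groups({"a": [1, 2, 3], "b": [1, 2, 3]}, paired=True)
        assert res[0].test_name == "wilcoxon"
        assert res[0].p_value == 1.0

    def test_mann_whitney_extreme_separation_exact(self):
        # n=3 vs 3: the most extreme ranking; exact one-sided p = 1/C(6,3) = 0.05,
        # two-sided p = 0.1
        res = compare_groups({"a": [1, 2, 3], "b": [101, 102, 103]})
        assert res[0].test_name == "mann-whitney-u"
        assert res[0].p_value == pytest.approx(0.1)
        one_sided = stats.mannwhitneyu([1, 2, 3], [101, 102, 103],
                                       alternative="less", method="exact").pvalue
        assert one_sided == pytest.approx(1 / 20)

    def test_kruskal_then_dunn_for_many_groups(self):
        rng = np.random.default_rng(3)
        groups = {k: rng.normal(loc, 1, 20) for k, loc in
                  [("a", 0), ("b", 0), ("c", 2), ("d", 0)]}
        res = compare_groups(groups)
        assert res[0].test_name == "kruskal-wallis"
        dunn = [r for r in res if r.test_name == "dunn"]
        assert len(dunn) == 6
        assert all(r.adjusted for r in dunn)

    def test_friedman_for_many_paired_groups(self):
        rng = np.random.default_rng(4)
        groups = {k: rng.normal(0, 1, 12) for k in "abc"}
        res = compare_groups(groups, paired=True)
        assert res[0].test_name == "friedman"

    def test_empty_group_rejected(self):
        with pytest.raises(HeterogeneityError):
            compare_groups({"a": [1], "b": []})

    def test_unequal_paired_lengths_rejected(self):
        with pytest.raises(HeterogeneityError):
            compare_groups({"a": [1, 2], "b": [1]}, paired=True)

    def test_all_identical_values_give_p_one_not_crash(self):
        for paired in (False, True):
            res = compare_groups({"a": [5.0] * 4, "b": [5.0] * 4, "c": [5.0] * 4},
                                 paired=paired)
            assert res[0].p_value == 1.0


class TestDunn:
    def test_adjusted_p_never_below_unadjusted(self):
        rng = np.random.default_rng(5)
        groups = {k: rng.normal(i * 0.5, 1, 15) for i, k in enumerate("abcd")}
        tab = dunn_posthoc(groups)
        assert (tab["p_adjusted"] >= tab["p_unadjusted"] - 1e-15).all()
        assert (tab["p_adjusted"] <= 1.0).all()

    def test_two_group_dunn_matches_normal_approx_ranksum(self):
        # with two groups Dunn's z test reduces to the rank-sum z statistic
        a = [1.0, 4.0, 6.0, 10.0]
        b = [2.0, 8.0, 12.0, 14.0, 20.0]
        tab = dunn_posthoc({"a": a, "b": b})
        n1, n2, n = len(a), len(b), len(a) + len(b)
        ranks = stats.rankdata(a + b)
        z_expected = (ranks[:n1].mean() - ranks[n1:].mean()) / np.sqrt(
            n * (n + 1) / 12 * (1 / n1 + 1 / n2)
        )
        assert tab.loc[0, "z"] == pytest.approx(z_expected)


class TestCorrelate:
    def test_monotone_identity_spearman(self):
        r = correlate([1, 2, 3, 4, 5], [10, 20, 30, 40, 50], "spearman")
        assert r.coefficient == pytest.approx(1.0)

    def test_kendall_tau_b_against_pair_enumeration(self):
        x, y = [1, 2, 3, 4], [2, 1, 4, 3]
        conc = disc = 0
        for (i, j) in itertools.combinations(range(4), 2):
            s = (x[j] - x[i]) * (y[j] - y[i])
            conc += s > 0
            disc += s < 0
        assert (conc, disc) == (4, 2)
        r = correlate(x, y, "kendall_tau_b")
        assert r.coefficient == pytest.approx((conc - disc) / 6)  # = 1/3, no ties

    def test_phi_perfect_concordance(self):
        r = correlate([0, 0, 1, 1] * 5, [0, 0, 1, 1] * 5, "phi")
        assert r.coefficient == pytest.approx(1.0)

    def test_phi_sign_for_discordant_table(self):
        r = correlate([0, 0, 1, 1] * 5, [1, 1, 0, 0] * 5, "phi")
        assert r.coefficient == pytest.approx(-1.0)

    def test_zero_variance_reports_undefined(self):
        r = correlate([1, 1, 1], [1, 2, 3], "spearman")
        assert not r.defined
        assert r.note == "zero variance"

    def test_fisher_z_interval_brackets_coefficient(self):
        r = correlate([1, 2, 3, 4, 5, 6], [2, 1, 4, 3, 6, 5], "spearman")
        assert r.ci_low <= r.coefficient <= r.ci_high

    def test_fisher_z_too_small_n_is_nan(self):
        lo, hi = fisher_z_ci(0.5, 3)
        assert np.isnan(lo) and np.isnan(hi)

    def test_unknown_kind_rejected(self):
        with pytest.raises(HeterogeneityError):
            correlate([1, 2], [1, 2], "pearson")
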