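"""Scoring formulas, QC rule, category boundaries and lesion aggregation."""

import bisect

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pdl1het.scoring import (
    CoreCounts,
    PDL1Score,
    ScoringError,
    UndefinedScoreError,
    aggregate_lesion,
    aggregate_lesions,
    categorize,
    categorize_series,
    compute_scores,
    score_cores,
)


def _core(viable, tumor_pos, immune_pos, idx=1):
    return CoreCounts("c", "l", "p", viable, tumor_pos, immune_pos, idx)


class TestComputeScores:
    @pytest.mark.parametrize(
        "viable, tpos, ipos, cps, tps, cps_raw, qc",
        [
            (200, 0, 0, 0.0, 0.0, 0.0, True),  # zero positives
            (100, 100, 40, 100.0, 100.0, 140.0, True),  # cap at 100
            (200, 10, 6, 8.0, 5.0, 8.0, True),  # hand arithmetic
            (80, 8, 0, 10.0, 10.0, 10.0, False),  # below 100-cell QC rule
            (150, 150, 0, 100.0, 100.0, 100.0, True),  # fully positive tumor
        ],
    )
    def test_examples(self, viable, tpos, ipos, cps, tps, cps_raw, qc):
        s = compute_scores(_core(viable, tpos, ipos))
        assert s.cps == pytest.approx(cps)
        assert s.tps == pytest.approx(tps)
        assert s.cps_raw == pytest.approx(cps_raw)
        assert s.qc_pass is qc

    def test_zero_viable_cells_is_undefined_not_qc_failure(self):
        with pytest.raises(UndefinedScoreError):
            compute_scores(_core(0, 0, 0))

    def test_more_positive_than_viable_rejected(self):
        with pytest.raises(ScoringError):
            _core(100, 101, 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ScoringError):
            _core(100, -1, 0)

    @given(
        viable=st.integers(1, 5000),
        tpos_frac=st.floats(0, 1),
        ipos=st.integers(0, 5000),
    )
    @settings(max_examples=200, deadline=None)
    def test_score_ordering_invariant(self, viable, tpos_frac, ipos):
        """0 <= TPS <= CPS <= 100 for every valid core."""
        tpos = int(tpos_frac * viable)
        s = compute_scores(_core(viable, tpos, ipos))
        assert 0.0 <= s.tps <= s.cps <= 100.0
        assert s.cps == min(s.cps_raw, 100.0)

    @given(viable=st.integers(1, 2000), tpos_frac=st.floats(0, 1), ipos=st.integers(0, 200))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_immune_positives(self, viable, tpos_frac, ipos):
        tpos = int(tpos_frac * viable)
        s0 = compute_scores(_core(viable, tpos, ipos))
        s1 = compute_scores(_core(viable, tpos, ipos + 1))
        assert s1.cps >= s0.cps
        assert s1.tps == s0.tps

    @given(viable=st.integers(2, 2000), tpos_frac=st.floats(0, 1), ipos=st.integers(0, 200))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_tumor_positives(self, viable, tpos_frac, ipos):
        tpos = min(int(tpos_frac * viable), viable - 1)
        s0 = compute_scores(_core(viable, tpos, ipos))
        s1 = compute_scores(_core(viable, tpos + 1, ipos))
        assert s1.cps >= s0.cps
        assert s1.tps >= s0.tps


def brute_force_category(value, scheme):
    """Independent oracle: locate the value among sorted boundaries."""
    edges = {"CPS": [1.0, 20.0], "TPS": [1.0, 50.0]}[scheme]
    return ("negative", "low", "high")[bisect.bisect_right(edges, value)]


class TestCategorize:
    GRID = [0, 0.5, 0.999, 1, 1.001, 19.999, 20, 49.999, 50, 100]

    @pytest.mark.parametrize("scheme", ["CPS", "TPS"])
    @pytest.mark.parametrize("value", GRID)
    def test_matches_bruteforce_oracle(self, value, scheme):
        assert categorize(value, scheme) == brute_force_category(value, scheme)

    @pytest.mark.parametrize(
        "value, scheme, label",
        [
            (0.5, "CPS", "negative"),
            (1, "CPS", "low"),
            (20, "CPS", "high"),
            (50, "TPS", "high"),
            (1, "TPS", "low"),
        ],
    )
    def test_threshold_values_go_to_upper_category(self, value, scheme, label):
        assert categorize(value, scheme) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ScoringError):
            categorize(101, "CPS")
        with pytest.raises(ScoringError):
            categorize(-0.1, "TPS")

    def test_vectorized_agrees_with_scalar(self):
        vals = np.array(self.GRID, dtype=float)
        for scheme in ("CPS", "TPS"):
            got = categorize_series(vals, scheme)
            expected = [categorize(v, scheme) for v in vals]
            assert list(got) == expected


def _score(cps, qc=True, viable=500):
    return PDL1Score(cps=cps, tps=cps, cps_raw=cps, qc_pass=qc, n_tumor_viable=viable)


class TestAggregateLesion:
    def test_identical_cores(self):
        les = aggregate_lesion([_score(10.0), _score(10.0)])
        assert les.score.cps == pytest.approx(10.0)

    def test_arithmetic_mean(self):
        les = aggregate_lesion([_score(0.0), _score(16.0)])
        assert les.score.cps == pytest.approx(8.0)

    def test_single_qc_survivor_carries_lesion(self):
        les = aggregate_lesion([_score(99.0, qc=False, viable=50), _score(30.0)])
        assert les.score.cps == pytest.approx(30.0)

    def test_no_qc_survivor_excludes_lesion(self):
        les = aggregate_lesion([_score(5.0, qc=False, viable=50)])
        assert les.excluded

    def test_empty_rejected(self):
        with pytest.raises(ScoringError):
            aggregate_lesion([])

    @given(st.lists(st.floats(0, 100), min_size=2, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariant(self, values):
        rng = np.random.default_rng(0)
        cores = [_score(v) for v in values]
        shuffled = list(cores)
        rng.shuffle(shuffled)
        assert aggregate_lesion(cores).score.cps == pytest.approx(
            aggregate_lesion(shuffled).score.cps
        )


class TestTableInterface:
    def test_score_cores_matches_scalar_path(self, small_cohort):
        cores, _ = small_cohort
        scored = score_cores(cores)
        sample = scored.sample(50, random_state=1)
        for row in sample.itertuples():
            s = compute_scores(
                CoreCounts(
                    row.core_id, row.lesion_id, row.patient_id,
                    row.n_tumor_viable, row.n_tumor_pos, row.n_immune_pos,
                    row.sample_index,
                )
            )
            assert row.cps == pytest.approx(s.cps)
            assert row.tps == pytest.approx(s.tps)
            assert row.qc_pass == s.qc_pass

    def test_aggregate_lesions_mean_over_passing_cores(self, small_cohort):
        cores, _ = small_cohort
        scored = score_cores(cores)
        lesions = aggregate_lesions(scored).set_index("lesion_id")
        some = scored[scored["qc_pass"]].groupby("lesion_id")["cps"].mean()
        pd.testing.assert_series_equal(
            lesions.loc[some.index, "cps"], some, check_names=False
        )

    def test_qc_failing_cores_scored_but_flagged(self):
        df = pd.DataFrame(
            [
                {"patient_id": "P", "lesion_id": "L", "lesion_type": "primary",
                 "treated": False, "core_id": "c1", "sample_index": 1,
                 "n_tumor_viable": 80, "n_tumor_pos": 8, "n_immune_pos": 0}
            ]
        )
        scored = score_cores(df)
        assert scored.loc[0, "tps"] == pytest.approx(10.0)
        assert not scored.loc[0, "qc_pass"]
        lesions = aggregate_lesions(scored)
        assert bool(lesions.loc[0, "excluded"])
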