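"""Noise floor, positivity rules, Fisher's exact test, screen and IP calls."""

import math
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from halobc import (
    ClusterParams,
    MoleculeCountTable,
    NoiseFloor,
    call_ip_series,
    call_ppi,
    call_screen,
    fisher_exact_two_tailed,
    noise_floor,
    summarize_screen,
)


def _table(unused_reads, extra=()):
    rows = [(f"unused_{i}", "unused", r, r, 0) for i, r in enumerate(unused_reads)]
    rows += list(extra)
    frame = pd.DataFrame(
        rows, columns=["protein", "role", "assigned_reads", "filtered_reads", "molecule_count"]
    )
    total = int(frame["assigned_reads"].sum())
    return MoleculeCountTable(frame=frame, total_reads=total, unassigned_reads=0)


def fisher_enumeration(a, b, c, d):
    """Independent oracle: direct hypergeometric enumeration over all
    tables with the observed margins, point-probability two-tailed rule."""
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, r1)

    def prob(x):
        return comb(c1, x) * comb(n - c1, r1 - x) / denom

    p_obs = prob(a)
    lo = max(0, r1 - (n - c1))
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-12))


class TestNoiseFloor:
    def test_all_zero_unused(self):
        floor = noise_floor(_table([0, 0, 0, 0]))
        assert floor.threshold == 0.0

    def test_hand_computed_sample_sd(self):
        # [2, 4, 6]: mean 4, sample SD (n-1) = 2, threshold 4 + 3*2 = 10
        floor = noise_floor(_table([2, 4, 6]))
        assert floor.unused_mean == pytest.approx(4.0)
        assert floor.unused_sd == pytest.approx(2.0)
        assert floor.threshold == pytest.approx(10.0)

    def test_undefined_below_two_unused(self):
        with pytest.raises(ValueError, match="noise floor undefined"):
            noise_floor(_table([5]))

    def test_clean_simulation_no_background_flags(self, sim_schema):
        from halobc import SimConfig, count_molecules, iter_observations, simulate_experiment

        names = [i.protein_name for i in sim_schema.identifiers if i.role == "assay"]
        cfg = SimConfig(
            schema=sim_schema,
            molecule_counts={names[0]: 60, names[1]: 40},
            pcr_error_rate=0.0,
            seq_error_rate=0.0,
            reads_out=1500,
            seed=5,
        )
        reads, _ = simulate_experiment(cfg)
        table = count_molecules(iter_observations(reads, sim_schema), sim_schema)
        floor = noise_floor(table)
        for name in names:
            call = call_ppi(table.reads_for(name), 0, floor)
            assert call.call != "background_noise"
            assert call.positive


class TestCallPpi:
    FLOOR = NoiseFloor(unused_mean=10.0, unused_sd=0.0)

    def test_below_ten_reads_is_negative(self):
        call = call_ppi(9, 0, self.FLOOR)
        assert call.call == "negative"
        assert call.rules_fired["min_reads"] is False

    def test_clear_positive(self):
        call = call_ppi(500, 20, self.FLOOR)
        assert call.positive
        assert all(call.rules_fired.values())

    def test_control_exceeding_prey_is_negative(self):
        call = call_ppi(50, 80, self.FLOOR)
        assert call.call == "negative"
        assert call.rules_fired["control_exceed"] is False

    def test_tie_with_control_is_negative(self):
        assert not call_ppi(50, 50, self.FLOOR).positive

    def test_background_noise_label(self):
        floor = NoiseFloor(unused_mean=100.0, unused_sd=0.0)
        call = call_ppi(60, 5, floor)
        assert call.call == "background_noise"

    def test_rules_subset(self):
        call = call_ppi(60, 5, floor=None, rules=("min_reads", "control_exceed"))
        assert call.positive
        assert "noise_floor" not in call.rules_fired

    def test_negative_reads_rejected(self):
        with pytest.raises(ValueError):
            call_ppi(-1, 0, self.FLOOR)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        prey=st.integers(0, 300),
        bump=st.integers(0, 300),
        control=st.integers(0, 200),
        floor_mean=st.floats(0, 150),
    )
    def test_monotone_in_prey_reads(self, prey, bump, control, floor_mean):
        """Increasing prey reads with everything else fixed never flips
        a positive call to negative."""
        floor = NoiseFloor(unused_mean=floor_mean, unused_sd=0.0)
        before = call_ppi(prey, control, floor)
        after = call_ppi(prey + bump, control, floor)
        if before.positive:
            assert after.positive


class TestFisher:
    def test_screen_table_printed_p(self):
        # the 7/16 vs 1/16 screen outcome
        assert fisher_exact_two_tailed(7, 9, 1, 15) == pytest.approx(0.0373, abs=5e-5)

    def test_balanced_table_p_one(self):
        assert fisher_exact_two_tailed(5, 5, 5, 5) == pytest.approx(1.0)

    def test_extreme_table_equals_enumeration(self):
        assert fisher_exact_two_tailed(8, 8, 0, 16) == pytest.approx(
            fisher_enumeration(8, 8, 0, 16), rel=1e-7
        )

    def test_symmetric_under_row_and_column_swap(self):
        assert fisher_exact_two_tailed(7, 9, 1, 15) == pytest.approx(
            fisher_exact_two_tailed(15, 1, 9, 7), rel=1e-9
        )

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_tailed(0, 0, 0, 0)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    def test_agrees_with_enumeration_oracle(self, a, b, c, d):
        """Implementation matches direct hypergeometric enumeration on
        every table with margins <= 40 (spans zero-margin edge cases)."""
        if a + b + c + d == 0:
            return
        assert fisher_exact_two_tailed(a, b, c, d) == pytest.approx(
            fisher_enumeration(a, b, c, d), rel=1e-7, abs=1e-12
        )


class TestSummarizeScreen:
    def _calls(self, positives, total):
        floor = NoiseFloor(0.0, 0.0)
        return [
            call_ppi(100 if i < positives else 0, 10, floor, protein=f"p{i}")
            for i in range(total)
        ]

    def test_screen_rates_and_p(self):
        s = summarize_screen(self._calls(7, 16), self._calls(1, 16))
        assert s.prs_rate == pytest.approx(0.4375)
        assert s.rrs_rate == pytest.approx(0.0625)
        assert s.p_two_tailed == pytest.approx(0.0373, abs=5e-5)

    def test_identical_lists_p_one(self):
        s = summarize_screen(self._calls(4, 10), self._calls(4, 10))
        assert s.p_two_tailed == pytest.approx(1.0)

    def test_perfect_separation_equals_enumeration(self):
        s = summarize_screen(self._calls(16, 16), self._calls(0, 16))
        assert s.p_two_tailed == pytest.approx(fisher_enumeration(16, 0, 0, 16), rel=1e-7)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            summarize_screen([], self._calls(1, 4))


class TestCallScreen:
    def test_sheet_driven_calls(self):
        extra = [
            ("preyA", "assay", 500, 480, 40),
            ("preyB", "assay", 4, 4, 2),
            ("halotag_only", "control", 20, 20, 5),
        ]
        table = _table([0, 1, 0, 1], extra=extra)
        sheet = pd.DataFrame(
            {
                "protein": ["preyA", "preyB"],
                "set": ["PRS", "RRS"],
                "control": ["halotag_only", "halotag_only"],
            }
        )
        calls, summary = call_screen(table, sheet)
        assert list(calls["call"]) == ["positive", "negative"]
        assert summary.prs_positive == 1 and summary.rrs_positive == 0

    def test_on_molecules_flag(self):
        extra = [
            ("preyA", "assay", 500, 480, 8),
            ("halotag_only", "control", 20, 20, 5),
        ]
        table = _table([0, 0], extra=extra)
        sheet = pd.DataFrame(
            {"protein": ["preyA"], "set": ["PRS"], "control": ["halotag_only"]}
        )
        calls, _ = call_screen(table, sheet, on="molecules")
        # 8 molecules < 10-read rule applied to molecule scale -> negative
        assert calls["call"].iloc[0] == "negative"


class TestIpSeries:
    def test_replicate_sum_positive(self):
        result = call_ip_series(
            [(1e4, {"oligo59": 100, "oligo60": 80, "oligo61": 90, "oligo62": 70})],
            {1e4: 50},
            serum_reference={1e4: 170},
        )
        row = result.steps.iloc[0]
        assert row["reads"] == 340
        assert row["call"] == "positive"
        assert row["specificity_ratio"] == pytest.approx(2.0)

    def test_control_exceeds_negative(self):
        result = call_ip_series([(1e4, [10, 10, 5, 5])], {1e4: 50})
        assert result.steps.iloc[0]["call"] == "negative"
        assert result.detection_limit is None

    def test_missing_control_uncallable(self):
        result = call_ip_series([(1e6, [100, 100, 100, 100])], {1e4: 50})
        assert result.steps.iloc[0]["call"] == "uncallable"

    def test_detection_limit_on_decaying_ladder(self):
        # 10-fold signal decay per step against a flat control of 200
        dilutions = [1e4, 1e5, 1e6, 1e7, 1e8]
        series = [(d, [int(4e9 / d)] * 4) for d in dilutions]
        controls = {d: 200 for d in dilutions}
        result = call_ip_series(series, controls)
        # positive while 4 * 4e9/d > 200, i.e. through 1e7
        assert result.detection_limit == 1e7
        assert list(result.steps["call"]) == [
            "positive", "positive", "positive", "positive", "negative",
        ]
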