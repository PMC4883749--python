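import math

import numpy as np
import pytest

from pbnfit.core import BooleanRule, Condition, ModelError, PBNModel
from pbnfit.selection import (CrosstalkCandidate, add_crosstalk, aic,
                              comparison_table, crosstalk_scan, f_test)
from pbnfit.synth import (planted_crosstalk_problem, simulate_dataset)
from pbnfit.selection import add_crosstalk as _add


class TestAic:
    def test_log_term_vanishes_when_sse_equals_n(self):
        assert aic(12.0, 12, 5) == pytest.approx(10.0)

    def test_reproduces_initial_no_crosstalk_value(self):
        """SSE 0.198 over the 30 training cells with 23 free weights."""
        assert aic(0.198, 30, 23) == pytest.approx(-104.62, abs=0.005)

    def test_reproduces_refined_no_crosstalk_value(self):
        """SSE 0.208 over 33 cells (3 extra pPKC points) with 25 weights."""
        assert aic(0.208, 33, 25) == pytest.approx(-117.20, abs=0.005)

    def test_increases_with_parameters(self):
        values = [aic(0.5, 20, k) for k in range(1, 6)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_zero_sse_returns_negative_infinity_with_warning(self):
        with pytest.warns(UserWarning):
            assert aic(0.0, 10, 2) == -math.inf


class TestFTest:
    def test_equal_sse_gives_zero_f_unit_p(self):
        F, p = f_test(0.5, 2, 0.5, 4, 20)
        assert F == 0.0
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        F, p = f_test(2.0, 1, 1.0, 2, 12)
        assert F == pytest.approx(10.0)
        assert 0 < p < 0.05

    def test_p_decreases_as_f_increases(self):
        ps = [f_test(base, 1, 1.0, 2, 12)[1] for base in (1.5, 2.0, 3.0, 5.0)]
        assert all(b < a for a, b in zip(ps, ps[1:]))

    def test_worse_full_model_warns_negative_f(self):
        with pytest.warns(UserWarning, match="worse"):
            F, p = f_test(1.0, 1, 1.2, 2, 12)
        assert F < 0
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_requires_nesting(self):
        with pytest.raises(ValueError):
            f_test(1.0, 3, 0.5, 3, 12)


class TestAddCrosstalk:
    def test_activation_adds_low_flag_or_route(self):
        base, true_candidate, _, _, _ = planted_crosstalk_problem()
        variant = add_crosstalk(base, true_candidate)
        rules = variant.rules["Y"]
        assert [r.flag for r in rules] == ["H", "L"]
        assert rules[1].expression.unparse() == "X"
        assert len(variant.free_parameters()) == len(base.free_parameters()) + 2

    def test_inhibition_gates_the_main_route(self):
        base, *_ = planted_crosstalk_problem()
        variant = add_crosstalk(base, CrosstalkCandidate(4, "X", "Y", "inhibition"))
        assert variant.rules["Y"][1].expression.unparse() == "R2 AND NOT X"

    def test_duplicate_edge_rejected(self):
        base, *_ = planted_crosstalk_problem()
        with pytest.raises(ModelError, match="duplicates"):
            add_crosstalk(base, CrosstalkCandidate(9, "R2", "Y", "activation"))

    def test_unknown_endpoint_rejected(self):
        base, *_ = planted_crosstalk_problem()
        with pytest.raises(ModelError, match="endpoint"):
            add_crosstalk(base, CrosstalkCandidate(9, "nope", "Y", "activation"))

    def test_existing_multi_rule_target_grows_by_one_parameter(self):
        base = PBNModel([
            BooleanRule("IN", "0", flag="INPUT"),
            BooleanRule("S", "IN", flag="FIXED"),
            BooleanRule("A", "IN", weight=0.7, flag="H"),
            BooleanRule("A", "NOT IN", weight=0.3, flag="L"),
        ])
        variant = add_crosstalk(base, CrosstalkCandidate(1, "S", "A", "activation"))
        assert len(variant.free_parameters()) == len(base.free_parameters()) + 1


class TestCrosstalkScan:
    def test_empty_candidate_list_gives_base_row_only(self):
        base, _, _, conditions, readouts = planted_crosstalk_problem()
        data = simulate_dataset(base, conditions, readouts, seed=0)
        rows = crosstalk_scan(base, [], data, conditions, n_eval=30, seed=0)
        assert len(rows) == 1
        assert rows[0].variant == "base"

    def test_single_scan_reports_f_against_base(self):
        base, true_candidate, decoys, conditions, readouts = planted_crosstalk_problem()
        truth = add_crosstalk(base, true_candidate, raw_weight=0.3)
        data = simulate_dataset(truth, conditions, readouts, noise_sd=0.02, seed=1)
        rows = crosstalk_scan(base, [true_candidate], data, conditions,
                              n_eval=250, seed=1)
        table = comparison_table(rows)
        assert list(table["variant"]) == ["base", "1"]
        planted = rows[1]
        assert planted.sse < rows[0].sse
        assert planted.f_statistic > 0
        assert planted.p_value < 0.05

    def test_pairwise_mode_enumerates_unordered_pairs(self):
        base, true_candidate, decoys, conditions, readouts = planted_crosstalk_problem()
        data = simulate_dataset(base, conditions, readouts, seed=2)
        candidates = [true_candidate, decoys[0], decoys[1]]
        rows = crosstalk_scan(base, candidates, data, conditions,
                              mode="pairwise", n_eval=60, seed=2)
        assert [r.variant for r in rows[1:]] == ["1+2", "1+3", "2+3"]

    def test_nesting_variant_never_much_worse_than_base(self):
        """Richer nested variants reach at least the base fit quality
        (up to optimiser noise at finite budget)."""
        base, true_candidate, decoys, conditions, readouts = planted_crosstalk_problem()
        data = simulate_dataset(base, conditions, readouts, noise_sd=0.05, seed=3)
        rows = crosstalk_scan(base, [true_candidate, *decoys], data, conditions,
                              n_eval=250, seed=3)
        base_sse = rows[0].sse
        for row in rows[1:]:
            assert row.sse <= base_sse + 0.02
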