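import numpy as np
import pytest

from pbnfit.core import BooleanRule, Condition, PBNModel
from pbnfit.fitting import (ParameterSpace, apply_parameters, fit, sse_cost,
                            summarize_top)
from pbnfit.steady import exact_stationary
from pbnfit.synth import default_conditions, generate_random_pbn, simulate_dataset, SyntheticSpec


@pytest.fixture
def hl_model():
    return PBNModel([
        BooleanRule("IN", "0", flag="INPUT"),
        BooleanRule("A", "IN", weight=0.9, flag="H"),
        BooleanRule("A", "NOT IN", weight=0.3, flag="L"),
    ])


class TestApplyParameters:
    def test_raw_weights_normalised(self, hl_model):
        model = apply_parameters(hl_model, np.array([0.9, 0.3]))
        assert [r.weight for r in model.rules["A"]] == pytest.approx([0.75, 0.25])

    def test_single_rule_node_stays_at_one(self, hl_model):
        model = apply_parameters(hl_model, np.array([0.9, 0.3]))
        assert model.rules["IN"][0].weight == 1.0

    def test_symmetric_h_rules(self):
        base = PBNModel([
            BooleanRule("B", "0", flag="INPUT"),
            BooleanRule("A", "B", weight=0.6, flag="H"),
            BooleanRule("A", "NOT B", weight=0.7, flag="H"),
        ])
        model = apply_parameters(base, np.array([0.5, 0.5]))
        assert [r.weight for r in model.rules["A"]] == pytest.approx([0.5, 0.5])

    def test_out_of_bounds_clipped_with_warning(self, hl_model):
        with pytest.warns(UserWarning, match="clipped"):
            model = apply_parameters(hl_model, np.array([1.4, 0.2]))
        assert [r.weight for r in model.rules["A"]] == pytest.approx([1 / 1.2, 0.2 / 1.2])

    def test_weights_always_sum_to_one(self, small_model_factory):
        model = small_model_factory(6, seed=5)
        space = ParameterSpace(model)
        rng = np.random.default_rng(0)
        theta = space.bounds[:, 0] + rng.random(space.dimension) * np.ptp(space.bounds, axis=1)
        applied = space.apply(theta)
        for name in applied.nodes:
            assert sum(r.weight for r in applied.rules[name]) == pytest.approx(1.0)

    def test_h_dominates_l_after_normalisation(self, small_model_factory):
        model = small_model_factory(6, seed=8)
        space = ParameterSpace(model)
        rng = np.random.default_rng(1)
        theta = space.bounds[:, 0] + rng.random(space.dimension) * np.ptp(space.bounds, axis=1)
        applied = space.apply(theta)
        for name in applied.nodes:
            h = [r.weight for r in applied.rules[name] if r.flag == "H"]
            low = [r.weight for r in applied.rules[name] if r.flag == "L"]
            if h and low:
                assert min(h) >= max(low)


class TestSSECost:
    def test_perfect_fit_costs_zero(self, hl_model, dataset_builder):
        condition = Condition("on", {"IN": 1})
        truth = exact_stationary(apply_parameters(hl_model, np.array([0.75, 0.25])),
                                 condition)["A"]
        data = dataset_builder([("on", "A", truth, 0.05)])
        assert sse_cost(hl_model, np.array([0.75, 0.25]), data, [condition]) \
            == pytest.approx(0.0, abs=1e-12)

    def test_two_cells_off_by_point_one(self, hl_model, dataset_builder):
        condition = Condition("on", {"IN": 1})
        fitted = apply_parameters(hl_model, np.array([0.75, 0.25]))
        truth = exact_stationary(fitted, condition)["A"]
        cond0 = Condition("off", {"IN": 0})
        truth0 = exact_stationary(fitted, cond0)["A"]
        data = dataset_builder([("on", "A", truth - 0.1, 0.05),
                                ("off", "A", truth0 + 0.1, 0.05)])
        cost = sse_cost(hl_model, np.array([0.75, 0.25]), data, [condition, cond0])
        assert cost == pytest.approx(0.02, abs=1e-9)

    def test_dataset_condition_without_clamps_rejected(self, hl_model, dataset_builder):
        data = dataset_builder([("nowhere", "A", 0.5, 0.05)])
        with pytest.raises(Exception, match="nowhere"):
            sse_cost(hl_model, np.array([0.75, 0.25]), data, [])


class TestFit:
    def _problem(self, seed=7):
        spec = SyntheticSpec(n_nodes=5, noise_sd=0.0, seed=seed)
        truth = generate_random_pbn(spec)
        conditions = default_conditions(truth, 8, seed=seed)
        readouts = [n for n in truth.nodes if n not in truth.input_nodes()]
        data = simulate_dataset(truth, conditions, readouts, noise_sd=0.0, seed=seed)
        return truth, conditions, data

    def test_same_seed_identical_archive(self):
        truth, conditions, data = self._problem()
        a = fit(truth, data, conditions, n_eval=120, seed=4)
        b = fit(truth, data, conditions, n_eval=120, seed=4)
        assert np.array_equal(a.thetas, b.thetas)
        assert np.array_equal(a.sses, b.sses)

    def test_archive_size_equals_budget(self):
        truth, conditions, data = self._problem()
        result = fit(truth, data, conditions, n_eval=97, seed=1)
        assert len(result.sses) == 97
        assert result.best_sse == result.sses.min()

    @pytest.mark.parametrize("algorithm", ["de", "ea"])
    def test_best_so_far_non_increasing(self, algorithm):
        truth, conditions, data = self._problem()
        result = fit(truth, data, conditions, algorithm=algorithm,
                     n_eval=150, seed=2)
        running = np.minimum.accumulate(result.sses)
        assert (np.diff(running) <= 0).all()

    def test_recovers_single_identifiable_weight(self, dataset_builder):
        """One free weight pair, noiseless data: recovered within 0.05."""
        base = PBNModel([
            BooleanRule("IN", "0", flag="INPUT"),
            BooleanRule("A", "IN", weight=0.7, flag="H"),
            BooleanRule("A", "NOT IN", weight=0.3, flag="L"),
        ])
        conditions = [Condition("on", {"IN": 1}), Condition("off", {"IN": 0})]
        data = simulate_dataset(base, conditions, ["A"], noise_sd=0.0, seed=0)
        result = fit(base, data, conditions, n_eval=400, seed=3)
        recovered = result.space.normalised_weights(result.best_theta)
        assert recovered[0] == pytest.approx(0.7, abs=0.05)

    def test_zero_parameters_returns_fixed_cost(self, dataset_builder):
        model = PBNModel([BooleanRule("A", "1")])
        data = dataset_builder([("free", "A", 1 / 1.001, 0.05)])
        result = fit(model, data, [Condition("free", {})], n_eval=50, seed=0)
        assert result.space.dimension == 0
        assert result.best_sse == pytest.approx(0.0, abs=1e-9)


class TestSummarizeTop:
    def test_k_one_is_best_vector_with_zero_sd(self):
        spec = SyntheticSpec(n_nodes=5, noise_sd=0.0, seed=3)
        truth = generate_random_pbn(spec)
        conditions = default_conditions(truth, 6, seed=3)
        readouts = [n for n in truth.nodes if n not in truth.input_nodes()]
        data = simulate_dataset(truth, conditions, readouts, seed=3)
        result = fit(truth, data, conditions, n_eval=80, seed=5)
        summary = summarize_top(result, k=1)
        best = result.space.normalised_weights(result.best_theta)
        assert summary["mean"].values == pytest.approx(best)
        assert (summary["sd"] == 0).all()

    def test_k_above_archive_warns_and_uses_all(self):
        spec = SyntheticSpec(n_nodes=5, noise_sd=0.0, seed=3)
        truth = generate_random_pbn(spec)
        conditions = default_conditions(truth, 6, seed=3)
        readouts = [n for n in truth.nodes if n not in truth.input_nodes()]
        data = simulate_dataset(truth, conditions, readouts, seed=3)
        result = fit(truth, data, conditions, n_eval=60, seed=5)
        with pytest.warns(UserWarning, match="archive"):
            summary = summarize_top(result, k=10_000)
        assert len(summary) == result.space.dimension
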