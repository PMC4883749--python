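import numpy as np
import pytest

from pbnfit import pdgf
from pbnfit.core import Condition
from pbnfit.data import split_dataset
from pbnfit.steady import EstimatorSettings, estimate_marginals


@pytest.fixture(scope="module")
def conditions():
    return {c.name: c for c in pdgf.build_conditions()}


class TestStructure:
    def test_initial_variant_node_and_edge_counts(self):
        model = pdgf.build_pdgf_model("initial")
        assert len(model.nodes) == 27
        assert len(model.edges()) == 40

    @pytest.mark.parametrize("variant,k", [("initial", 23), ("refined", 25),
                                           ("final", 27)])
    def test_free_parameter_counts(self, variant, k):
        assert len(pdgf.build_pdgf_model(variant).free_parameters()) == k

    def test_variants_share_backbone(self):
        nodes = {v: pdgf.build_pdgf_model(v).nodes for v in pdgf.VARIANTS}
        assert nodes["initial"] == nodes["refined"] == nodes["final"]

    def test_final_adds_exactly_the_mek_crosstalk_edge(self):
        refined = pdgf.build_pdgf_model("refined").edges()
        final = pdgf.build_pdgf_model("final").edges()
        assert final - refined == {("PI3K", "MEK")}

    def test_candidate_table(self):
        candidates = pdgf.load_crosstalk_candidates()
        assert len(candidates) == 9
        assert [c.index for c in candidates] == list(range(1, 10))
        by_index = {c.index: c for c in candidates}
        assert by_index[4].source == "PI3K" and by_index[4].target == "MEK"
        assert by_index[7].sign == "inhibition"

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            pdgf.build_pdgf_model("imaginary")


class TestConditions:
    def test_ten_conditions_split_six_four(self, conditions):
        assert len(conditions) == 10
        from pbnfit.data import TRAIN_CONDITIONS, VALIDATION_CONDITIONS
        assert set(conditions) == set(TRAIN_CONDITIONS) | set(VALIDATION_CONDITIONS)

    def test_combined_condition_composes_clamps(self, conditions):
        clamps = conditions["DV-dPI3K+Wortmannin"].clamps
        assert clamps["PI3Krec"] == 0
        assert clamps["Wortmannin"] == 1
        assert clamps["DOX"] == 1

    def test_knockouts_clamp_recruitment_nodes(self, conditions):
        assert conditions["DV-dMAPK"].clamps["SHP2"] == 0
        assert conditions["DV-dPI3K"].clamps["PI3Krec"] == 0

    def test_nd_readouts_near_zero_without_basal_inputs(self):
        """No induction and no basal activity leaves every readout dark."""
        model = pdgf.build_pdgf_model("initial")
        nd = Condition("ND-nobasal", {"DOX": 0, "Wortmannin": 0, "U0126": 0,
                                      "GF109": 0, "Go6976": 0,
                                      "bPTEN": 0, "bPDK": 0})
        est = estimate_marginals(model, nd, list(pdgf.READOUT_NODES.values()),
                                 seed=0)
        for node, value in est.marginals.items():
            assert value < 0.05, node


class TestSyntheticStandIn:
    def test_layout_matches_study_shape(self):
        data = pdgf.synthetic_study_dataset(seed=1, scheme="refined")
        train, valid = data.subset("train"), data.subset("validation")
        assert len(train) == 33
        assert len(valid) == 20
        assert set(valid.frame["molecule"]) == set(pdgf.READOUTS)

    def test_negative_control_phospho_cells_are_zero(self):
        data = pdgf.synthetic_study_dataset(seed=1, scheme="refined")
        nd = data.frame[data.frame["condition"] == "ND"]
        phospho = nd[nd["molecule"] != "pPKC"]
        assert (phospho["mean"] == 0.0).all()
        # basal PKC is active without induction in the refined description
        assert nd[nd["molecule"] == "pPKC"]["mean"].iloc[0] > 0.9

    def test_noise_truncated_to_unit_interval(self):
        data = pdgf.synthetic_study_dataset(seed=2, noise_sd=0.3)
        assert (data.frame["mean"] >= 0).all()
        assert (data.frame["mean"] <= 1).all()


class TestQualitativeBehaviour:
    settings = EstimatorSettings(r=0.02, s=0.95, pilot=1000)

    def test_wortmannin_lowers_perk_only_with_crosstalk(self, conditions):
        """The final model transmits PI3K inhibition to ERK; the initial
        (no-crosstalk) variant cannot separate the two conditions."""
        final = pdgf.reference_model()
        on = estimate_marginals(final, conditions["DV-WT"], ["ERK"],
                                self.settings, seed=1)["ERK"]
        treated = estimate_marginals(final, conditions["DV-WT+Wortmannin"],
                                     ["ERK"], self.settings, seed=2)["ERK"]
        assert on - treated > 0.1

        initial = pdgf.build_pdgf_model("initial")
        on0 = estimate_marginals(initial, conditions["DV-WT"], ["ERK"],
                                 self.settings, seed=3)["ERK"]
        treated0 = estimate_marginals(initial, conditions["DV-WT+Wortmannin"],
                                      ["ERK"], self.settings, seed=4)["ERK"]
        assert abs(on0 - treated0) <= 2 * self.settings.r

    def test_dmapk_partially_lowers_perk_and_pplcg(self, conditions):
        final = pdgf.reference_model()
        wt = estimate_marginals(final, conditions["DV-WT"], ["ERK", "PLCg"],
                                self.settings, seed=5)
        km = estimate_marginals(final, conditions["DV-dMAPK"], ["ERK", "PLCg"],
                                self.settings, seed=6)
        for node in ("ERK", "PLCg"):
            assert km[node] < wt[node] - 0.1   # reduced...
            assert km[node] > 0.2              # ...but only partially


class TestEvaluatePredictions:
    def test_all_within_vacuous_sd(self, dataset_builder, conditions):
        data = dataset_builder(
            [(c, m, 0.5, 1.0, "validation")
             for c in ("DV-dMAPK+Wortmannin", "DV-dPI3K+U0126")
             for m in ("pERK", "pAKT")])
        report = pdgf.evaluate_predictions(pdgf.reference_model(), data,
                                           seed=0)
        assert report.n_total == 4
        assert report.n_within == 4

    def test_self_consistent_generator_round_trip(self):
        """Zero-noise data from the model itself scores (nearly) everywhere
        within an SD of 0.05."""
        data = pdgf.synthetic_study_dataset(seed=3, noise_sd=0.0, sd=0.05)
        report = pdgf.evaluate_predictions(pdgf.reference_model(),
                                           data.subset("validation"), seed=4)
        assert report.n_total == 20
        assert report.n_within == 20

    def test_missing_sd_excluded_and_listed(self, dataset_builder, conditions):
        data = dataset_builder([
            ("DV-dMAPK+U0126", "pERK", 0.5, np.nan, "validation"),
            ("DV-dMAPK+U0126", "pAKT", 0.5, 1.0, "validation")])
        report = pdgf.evaluate_predictions(pdgf.reference_model(), data, seed=0)
        assert report.n_total == 1
        assert len(report.excluded) == 1
        assert report.excluded["molecule"].iloc[0] == "pERK"
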