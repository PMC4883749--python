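import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pbnfit.data import (DataError, NormalisedDataset, RawBlotMeasurement,
                         normalise_raw, parse_model_text, split_dataset,
                         write_model_text, TRAIN_CONDITIONS, VALIDATION_CONDITIONS)


def raw(blot, condition, molecule, bio, tech, signal, tubulin, cal=False):
    return RawBlotMeasurement(blot, condition, molecule, bio, tech,
                              signal, tubulin, cal)


def with_calibrator(rows, blot="b1", molecule="pERK", value=1.0, tubulin=1.0):
    return rows + [raw(blot, "CAL", molecule, 0, t, value * tubulin, tubulin,
                       cal=True) for t in (1, 2, 3)]


class TestNormaliseRaw:
    def test_low_tubulin_point_discarded(self):
        """Tubulin at 10% of the blot maximum fails the 20% QC cut."""
        rows = with_calibrator([
            raw("b1", "A", "pERK", 1, 1, 5.0, 10.0),    # tubulin 10 vs max 100
            raw("b1", "B", "pERK", 1, 1, 5.0, 100.0),
        ], tubulin=100.0)
        data = normalise_raw(rows)
        assert set(data.frame["condition"]) == {"B"}

    def test_self_normalisation_yields_one(self):
        """signal/tubulin identical to the calibrator ratio gives 1.0."""
        rows = with_calibrator([raw("b1", "A", "pERK", 1, 1, 2.0, 2.0)])
        data = normalise_raw(rows)
        assert data.frame["mean"].tolist() == pytest.approx([1.0])

    def test_max_normalisation(self):
        """Calibrated ratios {0.5, 2.0} become means {0.25, 1.0}."""
        rows = with_calibrator([
            raw("b1", "A", "pERK", 1, 1, 0.5, 1.0),
            raw("b1", "B", "pERK", 1, 1, 2.0, 1.0),
        ])
        data = normalise_raw(rows)
        by_cond = dict(zip(data.frame["condition"], data.frame["mean"]))
        assert by_cond == pytest.approx({"A": 0.25, "B": 1.0})

    def test_technical_replicates_averaged_before_pooling(self):
        rows = with_calibrator([
            raw("b1", "A", "pERK", 1, 1, 1.0, 1.0),
            raw("b1", "A", "pERK", 1, 2, 3.0, 1.0),   # bio rep 1 mean: 2.0
            raw("b1", "A", "pERK", 2, 1, 4.0, 1.0),   # bio rep 2 mean: 4.0
        ])
        data = normalise_raw(rows)
        row = data.frame.iloc[0]
        assert row["mean"] == pytest.approx(1.0)      # 3 / max 3
        assert row["n"] == 2
        # sample SD of {2, 4} scaled by the max (3.0)
        assert row["sd"] == pytest.approx(np.std([2, 4], ddof=1) / 3.0)

    def test_missing_calibrator_raises(self):
        with pytest.raises(DataError, match="calibrator"):
            normalise_raw([raw("b1", "A", "pERK", 1, 1, 1.0, 1.0)])

    def test_calibrator_optional_variant(self):
        data = normalise_raw([raw("b1", "A", "pERK", 1, 1, 2.0, 4.0)],
                             calibrate=False)
        assert data.frame["mean"].tolist() == pytest.approx([1.0])

    def test_qc_is_per_blot(self):
        """A strong tubulin on one blot never evicts points on another."""
        rows = with_calibrator(with_calibrator([
            raw("b1", "A", "pERK", 1, 1, 1.0, 1.0),     # max tubulin on b1 is 1.0
            raw("b2", "B", "pERK", 1, 1, 1.0, 100.0),
        ]), blot="b2", tubulin=100.0)
        data = normalise_raw(rows)
        assert set(data.frame["condition"]) == {"A", "B"}

    @settings(max_examples=25, derandomize=True)
    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, scale):
        """Rescaling all intensities on a blot leaves the output unchanged."""
        rows = with_calibrator([
            raw("b1", "A", "pERK", 1, 1, 0.5, 1.0),
            raw("b1", "B", "pERK", 1, 1, 2.0, 0.8),
        ])
        scaled = [RawBlotMeasurement(m.blot, m.condition, m.molecule, m.bio_rep,
                                     m.tech_rep, m.signal * scale,
                                     m.tubulin * scale, m.is_calibrator)
                  for m in rows]
        a, b = normalise_raw(rows), normalise_raw(scaled)
        assert a.frame["mean"].values == pytest.approx(b.frame["mean"].values)


class TestSplitDataset:
    def _full_dataset(self, builder, with_pkc=True):
        rows = []
        for condition in TRAIN_CONDITIONS + VALIDATION_CONDITIONS:
            for molecule in ("pSTAT5", "pPDGFR", "pPLCg", "pERK", "pAKT"):
                rows.append((condition, molecule, 0.5, 0.1))
        if with_pkc:
            for condition in ("ND", "DV-WT", "DV-WT+Wortmannin"):
                rows.append((condition, "pPKC", 0.9, 0.1))
        return builder(rows)

    def test_base_scheme_counts(self, dataset_builder):
        train, valid = split_dataset(self._full_dataset(dataset_builder), "base")
        assert len(set(train.frame["condition"])) == 6
        assert len(set(valid.frame["condition"])) == 4
        assert len(train) == 30 and len(valid) == 20

    def test_refined_scheme_adds_three_points(self, dataset_builder):
        data = self._full_dataset(dataset_builder)
        base_train, _ = split_dataset(data, "base")
        refined_train, _ = split_dataset(data, "refined")
        assert len(refined_train) == len(base_train) + 3
        extra = refined_train.frame[refined_train.frame["molecule"] == "pPKC"]
        assert sorted(extra["condition"]) == ["DV-WT", "DV-WT+Wortmannin", "ND"]

    def test_empty_dataset_splits_to_empty(self, dataset_builder):
        train, valid = split_dataset(dataset_builder([]), "base")
        assert len(train) == 0 and len(valid) == 0

    def test_unknown_condition_listed_in_error(self, dataset_builder):
        data = dataset_builder([("mystery", "pERK", 0.5, 0.1)])
        with pytest.raises(DataError, match="mystery"):
            split_dataset(data, "base")


class TestModelText:
    def test_flags_parsed(self):
        model = parse_model_text("MEK = Raf , H\nMEK = PI3K , L\nRaf = MEK\nPI3K = Raf\n")
        assert [r.flag for r in model.rules["MEK"]] == ["H", "L"]

    def test_syntax_error_reports_line(self):
        with pytest.raises(DataError, match="line 1"):
            parse_model_text("X = Y AND NOT\nY = X\n")

    def test_undeclared_node_reports_line(self):
        with pytest.raises(DataError, match="line 2.*Z"):
            parse_model_text("X = X\nY = Z\n")

    def test_round_trip_identity(self, small_model_factory):
        model = small_model_factory(6, seed=9)
        again = parse_model_text(write_model_text(model), p=model.p)
        assert again.nodes == model.nodes
        for name in model.nodes:
            got = [(r.expression.unparse(), r.flag, pytest.approx(r.weight))
                   for r in again.rules[name]]
            want = [(r.expression.unparse(), r.flag, r.weight)
                    for r in model.rules[name]]
            assert got == want


class TestNormalisedDataset:
    def test_out_of_range_mean_rejected(self):
        frame = pd.DataFrame([{"condition": "A", "molecule": "x", "mean": 1.2,
                               "sd": 0.1, "n": 3, "split": "train"}])
        with pytest.raises(DataError):
            NormalisedDataset(frame)
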