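import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varcallkit.assay_io import (
    AssayDataset,
    AssayLoadError,
    Control,
    Measurement,
    NormalizationError,
    VariantParseError,
    normalize_activities,
    parse_variant,
    read_assay_table,
    validate_dataset,
)


class TestParseVariant:
    @pytest.mark.parametrize(
        "label, expected",
        [
            ("M1775R", (("M", 1775, "R"),)),
            ("C1787S/G1788D", (("C", 1787, "S"), ("G", 1788, "D"))),
            ("T1394I", (("T", 1394, "I"),)),
        ],
    )
    def test_valid_labels(self, label, expected):
        spec = parse_variant(label)
        assert spec.substitutions == expected
        assert spec.label == label

    def test_compound_is_single_unit(self):
        spec = parse_variant("C1787S/G1788D")
        assert spec.is_compound and len(spec.substitutions) == 2

    @pytest.mark.parametrize(
        "label", ["M0R", "", "1775R", "M1775", "X1775R", "M1775B", "MR", "M-5R"]
    )
    def test_malformed_labels_raise(self, label):
        with pytest.raises(VariantParseError):
            parse_variant(label)

    def test_error_names_the_token(self):
        with pytest.raises(VariantParseError, match="M0R"):
            parse_variant("A1775G/M0R")


def _m(variant, batch, firefly, renilla, control=Control.NONE, replicate=1,
       experiment="e1"):
    return Measurement(
        variant=variant, batch_id=batch, experiment_id=experiment,
        replicate=replicate, control=control, firefly=firefly, renilla=renilla,
    )


class TestNormalization:
    def test_wt_at_batch_mean_gets_zero(self):
        ds = normalize_activities(
            [_m("WT", "b1", 100.0, 10.0, Control.WT)]
        )
        assert ds.measurements[0].normalized_activity == pytest.approx(0.0)

    def test_half_wt_ratio_gives_log_half(self):
        ds = normalize_activities(
            [
                _m("WT", "b1", 100.0, 10.0, Control.WT),
                _m("V1", "b1", 50.0, 10.0),
            ]
        )
        y = {m.variant: m.normalized_activity for m in ds.measurements}
        assert y["V1"] == pytest.approx(math.log(0.5))

    def test_batch_invariance_of_centering(self):
        # same variant/WT fold-change in two batches with different WT levels
        ds = normalize_activities(
            [
                _m("WT", "b1", 100.0, 10.0, Control.WT),
                _m("V1", "b1", 30.0, 10.0),
                _m("WT", "b2", 400.0, 10.0, Control.WT),
                _m("V1", "b2", 120.0, 10.0),
            ]
        )
        y = [m.normalized_activity for m in ds.measurements if m.variant == "V1"]
        assert y[0] == pytest.approx(y[1])

    def test_idempotent(self):
        raw = [
            _m("WT", "b1", 100.0, 10.0, Control.WT),
            _m("V1", "b1", 55.0, 10.0),
        ]
        once = normalize_activities(raw)
        twice = normalize_activities(list(once.measurements))
        assert [m.normalized_activity for m in once.measurements] == [
            m.normalized_activity for m in twice.measurements
        ]

    def test_wt_mean_zero_per_batch(self):
        raw = [
            _m("WT", "b1", 90.0, 9.0, Control.WT, replicate=1),
            _m("WT", "b1", 130.0, 11.0, Control.WT, replicate=2),
            _m("WT", "b1", 70.0, 10.0, Control.WT, replicate=3),
        ]
        ds = normalize_activities(raw)
        assert np.mean(ds.y) == pytest.approx(0.0, abs=1e-12)

    def test_missing_wt_is_an_error_naming_the_batch(self):
        with pytest.raises(NormalizationError, match="b9"):
            normalize_activities([_m("V1", "b9", 50.0, 10.0)])

    @given(factor=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_multiplicative_batch_shift_invariance(self, factor):
        base = [
            _m("WT", "b1", 100.0, 10.0, Control.WT),
            _m("V1", "b1", 42.0, 10.0),
        ]
        shifted = [
            _m(m.variant, m.batch_id, m.firefly * factor, m.renilla,
               m.control) for m in base
        ]
        y0 = [m.normalized_activity for m in normalize_activities(base).measurements]
        y1 = [m.normalized_activity for m in normalize_activities(shifted).measurements]
        assert y0 == pytest.approx(y1, rel=1e-9, abs=1e-9)


class TestMeasurementAndDataset:
    def test_exactly_one_representation_required(self):
        with pytest.raises(AssayLoadError):
            Measurement(variant="V", batch_id="b", experiment_id="e",
                        replicate=1, firefly=10.0, renilla=1.0,
                        normalized_activity=0.5)
        with pytest.raises(AssayLoadError):
            Measurement(variant="V", batch_id="b", experiment_id="e", replicate=1)

    def test_nonpositive_renilla_rejected(self):
        with pytest.raises(AssayLoadError):
            _m("V", "b", 10.0, 0.0)

    def test_duplicate_key_rejected(self):
        m = Measurement(variant="V", batch_id="b", experiment_id="e",
                        replicate=1, normalized_activity=0.0)
        with pytest.raises(AssayLoadError, match="duplicated"):
            AssayDataset(measurements=(m, m))


class TestReadAssayTable:
    def test_raw_table_roundtrip(self, tmp_path):
        p = tmp_path / "assay.tsv"
        p.write_text(
            "variant\tbatch_id\texperiment_id\treplicate\tfirefly\trenilla\tcontrol\n"
            + "\n".join(
                f"V{i}\tb1\te1\t{i}\t{10 * i}\t10\tnone" for i in range(1, 7)
            )
            + "\n"
        )
        ms = read_assay_table(p, dialect="tsv")
        assert len(ms) == 6
        assert all(not m.is_normalized for m in ms)
        assert ms[2].row == 3

    def test_normalized_only_table(self, tmp_path):
        p = tmp_path / "assay.tsv"
        p.write_text(
            "variant\tbatch_id\texperiment_id\treplicate\tnormalized_activity\n"
            "V1\tb1\te1\t1\t-0.7\n"
        )
        (m,) = read_assay_table(p)
        assert m.is_normalized and m.firefly is None

    def test_zero_renilla_errors_with_row_number(self, tmp_path):
        p = tmp_path / "assay.tsv"
        p.write_text(
            "variant\tbatch_id\texperiment_id\treplicate\tfirefly\trenilla\n"
            "V1\tb1\te1\t1\t10\t5\n"
            "V2\tb1\te1\t1\t10\t0\n"
        )
        with pytest.raises(AssayLoadError, match="row 2"):
            read_assay_table(p)

    def test_missing_column_errors(self, tmp_path):
        p = tmp_path / "assay.tsv"
        p.write_text("variant\tfirefly\trenilla\nV1\t10\t5\n")
        with pytest.raises(AssayLoadError, match="batch_id"):
            read_assay_table(p)

    def test_non_numeric_reading_errors(self, tmp_path):
        p = tmp_path / "assay.tsv"
        p.write_text(
            "variant\tbatch_id\texperiment_id\treplicate\tfirefly\trenilla\n"
            "V1\tb1\te1\t1\tlots\t5\n"
        )
        with pytest.raises(AssayLoadError, match="row 1"):
            read_assay_table(p)


class TestValidateDataset:
    def _dataset(self, rows):
        ms = [
            Measurement(variant=v, batch_id=b, experiment_id=e, replicate=r,
                        control=c, normalized_activity=0.0)
            for v, b, e, r, c in rows
        ]
        return AssayDataset(measurements=tuple(ms))

    def test_triplicate_in_two_experiments_passes(self):
        rows = []
        for e, b in (("e1", "b1"), ("e2", "b2")):
            rows += [("V1", b, e, r, Control.NONE) for r in (1, 2, 3)]
            rows += [("WT", b, e, 1, Control.WT), ("NEG", b, e, 1, Control.NEG)]
        report = validate_dataset(self._dataset(rows))
        assert report.ok
        assert "V1" not in report.under_replicated

    def test_single_measurement_flagged(self):
        rows = [
            ("V1", "b1", "e1", 1, Control.NONE),
            ("WT", "b1", "e1", 1, Control.WT),
            ("NEG", "b1", "e1", 1, Control.NEG),
        ]
        report = validate_dataset(self._dataset(rows))
        assert "V1" in report.under_replicated

    def test_batch_without_neg_control_flagged(self):
        rows = [("WT", "b1", "e1", 1, Control.WT)]
        report = validate_dataset(self._dataset(rows))
        assert report.batches_missing_neg == ["b1"]
        assert not report.ok

    def test_dataset_not_mutated(self, small_sim):
        _, dataset, _, _ = small_sim
        before = tuple(dataset.measurements)
        validate_dataset(dataset)
        assert dataset.measurements == before
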