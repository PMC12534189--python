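import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from formucomet.formulation import (
    Catalogue,
    ComponentClass,
    DegradationLabel,
    Formulation,
    FormulationError,
    LabelSet,
    MoleculeRecord,
    degradation_label,
    l1_molar_distance,
    normalize_labels,
    validate_formulation,
    weight_ratio_to_np,
)
from formucomet import io as fio


def _form(pcts, ids=("IL-MC3", "HL-DOPE", "ST-CHOL", "PEG-C14"), **kw):
    return Formulation(components=tuple(zip(ids, pcts)), np_ratio=kw.pop("np_ratio", 6.0), **kw)


class TestValidation:
    def test_valid_four_component(self, catalogue):
        f = _form((35, 16, 46.5, 2.5))
        assert validate_formulation(f, catalogue) is f

    def test_molar_sum_violation_rejected(self, catalogue):
        with pytest.raises(FormulationError, match="molar sum"):
            validate_formulation(_form((35, 16, 46.5, 3.5)), catalogue)

    def test_small_deviation_renormalized(self, catalogue):
        f = validate_formulation(_form((35, 16, 46.505, 2.5)), catalogue)
        assert math.isclose(sum(f.molar_percents), 100.0, abs_tol=1e-9)

    def test_dual_ionizable_valid(self, catalogue):
        f = Formulation(
            components=(
                ("IL-CKK-E12", 30.0),
                ("IL-L319", 20.0),
                ("HL-DOPE", 16.0),
                ("ST-CHOL", 31.5),
                ("PEG-C14", 2.5),
            ),
            np_ratio=6.0,
        )
        assert validate_formulation(f, catalogue) is f

    def test_unknown_molecule(self, catalogue):
        with pytest.raises(FormulationError, match="unknown molecule"):
            validate_formulation(
                _form((35, 16, 46.5, 2.5), ids=("NOPE", "HL-DOPE", "ST-CHOL", "PEG-C14")),
                catalogue,
            )

    def test_missing_both_ratios(self, catalogue):
        f = Formulation(
            components=(("IL-MC3", 50.0), ("ST-CHOL", 50.0)), np_ratio=None
        )
        with pytest.raises(FormulationError, match="np_ratio"):
            validate_formulation(f, catalogue)


class TestNormalizeLabels:
    def test_decade_spaced_values(self):
        ls = LabelSet(
            task_id="t",
            formulation_ids=["a", "b", "c"],
            raw_values=[10.0, 100.0, 1000.0],
            plate_ids=["p", "p", "p"],
            standard_values={"p": 1.0},
        )
        out = normalize_labels(ls)
        assert out == pytest.approx({"a": 0.0, "b": 0.5, "c": 1.0})

    def test_plate_standard_division(self):
        # same ratios on two plates with different gains -> same labels
        ls = LabelSet(
            task_id="t",
            formulation_ids=["a", "b", "c", "d"],
            raw_values=[10.0, 1000.0, 50.0, 5000.0],
            plate_ids=["p1", "p1", "p2", "p2"],
            standard_values={"p1": 1.0, "p2": 5.0},
        )
        out = normalize_labels(ls)
        assert out["a"] == pytest.approx(out["c"])
        assert out["b"] == pytest.approx(out["d"])

    @pytest.mark.parametrize(
        "raw,std",
        [([5.0], {"p": 1.0}), ([3.0, 3.0, 3.0], {"p": 3.0})],
        ids=["single-value", "all-equal-to-standard"],
    )
    def test_degenerate_range(self, raw, std):
        ls = LabelSet(
            task_id="t",
            formulation_ids=[f"f{i}" for i in range(len(raw))],
            raw_values=raw,
            plate_ids=["p"] * len(raw),
            standard_values=std,
        )
        with pytest.raises(FormulationError, match="degenerate"):
            normalize_labels(ls)

    def test_nonpositive_raw(self):
        ls = LabelSet(
            task_id="t",
            formulation_ids=["a", "b"],
            raw_values=[-1.0, 2.0],
            plate_ids=["p", "p"],
            standard_values={"p": 1.0},
        )
        with pytest.raises(FormulationError, match="nonpositive"):
            normalize_labels(ls)

    def test_output_spans_unit_interval(self):
        rng = np.random.default_rng(0)
        raw = rng.lognormal(0, 2, 20).tolist()
        ls = LabelSet(
            task_id="t",
            formulation_ids=[f"f{i}" for i in range(20)],
            raw_values=raw,
            plate_ids=["p"] * 20,
            standard_values={"p": 1.0},
        )
        vals = np.array(list(normalize_labels(ls).values()))
        assert vals.min() == 0.0 and vals.max() == 1.0


class TestWeightRatioToNp:
    def test_hand_value(self):
        cat = Catalogue(
            [
                MoleculeRecord("il", "CCN", ComponentClass.IONIZABLE, 1, 710.0),
                MoleculeRecord("st", "CCO", ComponentClass.STEROL),
            ]
        )
        f = Formulation(
            components=(("il", 50.0), ("st", 50.0)), il_rna_weight_ratio=10.0
        )
        assert weight_ratio_to_np(f, cat) == pytest.approx(10 * 330 / 710, rel=1e-9)

    def test_linearity_in_weight_ratio(self):
        cat = Catalogue(
            [
                MoleculeRecord("il", "CCN", ComponentClass.IONIZABLE, 2, 500.0),
                MoleculeRecord("st", "CCO", ComponentClass.STEROL),
            ]
        )
        f1 = Formulation(components=(("il", 50.0), ("st", 50.0)), il_rna_weight_ratio=5.0)
        f2 = Formulation(components=(("il", 50.0), ("st", 50.0)), il_rna_weight_ratio=10.0)
        assert weight_ratio_to_np(f2, cat) == pytest.approx(2 * weight_ratio_to_np(f1, cat))

    def test_unity_when_moles_match(self):
        # MW == per-nt mass and one amine: weight ratio 1 gives N/P = 1
        cat = Catalogue(
            [
                MoleculeRecord("il", "CCN", ComponentClass.IONIZABLE, 1, 330.0),
                MoleculeRecord("st", "CCO", ComponentClass.STEROL),
            ]
        )
        f = Formulation(components=(("il", 50.0), ("st", 50.0)), il_rna_weight_ratio=1.0)
        assert weight_ratio_to_np(f, cat) == pytest.approx(1.0)

    def test_dual_ionizable_mass_split(self):
        # two identical ionizable lipids must behave like one
        cat = Catalogue(
            [
                MoleculeRecord("a", "CCN", ComponentClass.IONIZABLE, 1, 600.0),
                MoleculeRecord("b", "CCCN", ComponentClass.IONIZABLE, 1, 600.0),
                MoleculeRecord("st", "CCO", ComponentClass.STEROL),
            ]
        )
        dual = Formulation(
            components=(("a", 30.0), ("b", 20.0), ("st", 50.0)),
            il_rna_weight_ratio=10.0,
        )
        single = Formulation(
            components=(("a", 50.0), ("st", 50.0)), il_rna_weight_ratio=10.0
        )
        assert weight_ratio_to_np(dual, cat) == pytest.approx(
            weight_ratio_to_np(single, cat)
        )

    def test_missing_amine_count(self):
        cat = Catalogue(
            [
                MoleculeRecord("il", "CCN", ComponentClass.IONIZABLE, None, 710.0),
                MoleculeRecord("st", "CCO", ComponentClass.STEROL),
            ]
        )
        f = Formulation(components=(("il", 50.0), ("st", 50.0)), il_rna_weight_ratio=10.0)
        with pytest.raises(FormulationError, match="amine_count"):
            weight_ratio_to_np(f, cat)


class TestL1Distance:
    def test_identity(self, base_formulation):
        assert l1_molar_distance(base_formulation, base_formulation) == 0.0

    def test_hand_example(self):
        a = _form((35, 16, 46.5, 2.5))
        b = _form((40, 16, 41.5, 2.5))
        assert l1_molar_distance(a, b) == pytest.approx(10.0)

    def test_different_lipid_sets_counted_as_absent_slots(self):
        a = _form((50, 50), ids=("IL-MC3", "ST-CHOL"))
        b = _form((50, 50), ids=("IL-SM102", "ST-CHOL"))
        assert l1_molar_distance(a, b) == pytest.approx(100.0)

    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=4, max_size=4),
        st.lists(st.floats(0, 100, allow_nan=False), min_size=4, max_size=4),
        st.lists(st.floats(0, 100, allow_nan=False), min_size=4, max_size=4),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_triangle(self, pa, pb, pc):
        ids = ("w", "x", "y", "z")
        a, b, c = (
            Formulation(components=tuple(zip(ids, p)), np_ratio=1.0)
            for p in (pa, pb, pc)
        )
        dab = l1_molar_distance(a, b)
        assert dab == pytest.approx(l1_molar_distance(b, a))
        assert dab <= l1_molar_distance(a, c) + l1_molar_distance(c, b) + 1e-9


class TestDegradation:
    @pytest.mark.parametrize(
        "pre,post,expected", [(0.8, 0.8, 0.0), (0.9, 0.2, 0.7), (0.2, 0.9, -0.7)]
    )
    def test_subtraction(self, pre, post, expected):
        assert degradation_label(pre, post) == pytest.approx(expected)
        assert DegradationLabel(pre, post).degradation == pytest.approx(expected)


class TestRoundTrip:
    def test_formulation_table_round_trip(self, tmp_path, catalogue):
        fs = [
            _form((35, 16, 46.5, 2.5)).with_labels({"dc24": 0.25, "b16": 0.5}),
            Formulation(
                components=(
                    ("IL-CKK-E12", 30.123456),
                    ("IL-L319", 19.876544),
                    ("HL-DOPE", 16.0),
                    ("ST-CHOL", 31.5),
                    ("PEG-C14", 2.5),
                ),
                il_rna_weight_ratio=10.0,
                aqueous_organic_ratio="1:1",
                id="X1",
            ),
        ]
        path = tmp_path / "f.csv"
        fio.write_formulations(fs, path)
        back = fio.read_formulations(path)
        for orig, rt in zip(fs, back):
            assert rt.components == orig.components
            assert rt.np_ratio == orig.np_ratio
            assert rt.il_rna_weight_ratio == orig.il_rna_weight_ratio
            assert rt.aqueous_organic_ratio == orig.aqueous_organic_ratio
            assert rt.labels == orig.labels

    def test_catalogue_round_trip(self, tmp_path, catalogue):
        path = tmp_path / "cat.csv"
        fio.write_catalogue(catalogue, path)
        back = fio.read_catalogue(path)
        assert back.ids() == catalogue.ids()
        for rec in catalogue:
            rt = back[rec.id]
            assert rt.smiles == rec.smiles
            assert rt.component_class == rec.component_class
            assert rt.amine_count == rec.amine_count
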