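import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_profile, oh
from ohfa.profiles import (
    Basis,
    BasisError,
    Branching,
    CarbonRangeError,
    ConditionVariable,
    DegenerateInputError,
    FattyAcidDescriptor,
    FattyAcidParseError,
    Measurement,
    ValueKind,
    aggregate_replicates,
    class_totals,
    format_fa_name,
    normalize,
    parse_fa_name,
)


class TestDescriptor:
    def test_structural_equality(self):
        a = FattyAcidDescriptor(15, Branching.ANTEISO, 0, True)
        b = FattyAcidDescriptor(15, Branching.ANTEISO, 0, True)
        assert a == b and hash(a) == hash(b)

    def test_iso_needs_four_carbons(self):
        with pytest.raises(ValueError):
            FattyAcidDescriptor(3, Branching.ISO)

    def test_anteiso_needs_five_carbons(self):
        with pytest.raises(ValueError):
            FattyAcidDescriptor(4, Branching.ANTEISO)

    def test_unsaturation_bound(self):
        with pytest.raises(ValueError):
            FattyAcidDescriptor(10, Branching.NORMAL, 10)

    def test_carbon_range(self):
        with pytest.raises(CarbonRangeError):
            FattyAcidDescriptor(41)


class TestParse:
    @pytest.mark.parametrize(
        "label,expected",
        [
            ("anteiso 15:0", FattyAcidDescriptor(15, Branching.ANTEISO, 0, False)),
            ("16:1", FattyAcidDescriptor(16, Branching.NORMAL, 1, False)),
            ("i-C15", FattyAcidDescriptor(15, Branching.ISO, 0, False)),
            ("ai-C17", FattyAcidDescriptor(17, Branching.ANTEISO, 0, False)),
            ("3-OH ai-C17", FattyAcidDescriptor(17, Branching.ANTEISO, 0, True)),
            ("normal C_14", FattyAcidDescriptor(14, Branching.NORMAL, 0, False)),
            ("ISO 15:1", FattyAcidDescriptor(15, Branching.ISO, 1, False)),
        ],
    )
    def test_dialects(self, label, expected):
        assert parse_fa_name(label) == expected

    def test_context_default_sets_hydroxylation(self):
        got = parse_fa_name("iso C_17", hydroxylated_3=True)
        assert got == FattyAcidDescriptor(17, Branching.ISO, 0, True)

    def test_explicit_marker_overrides_default(self):
        got = parse_fa_name("3-OH n-C14", hydroxylated_3=False)
        assert got.hydroxylated_3

    @pytest.mark.parametrize("label", ["", "gibberish", "C", "iso", "15:1:2"])
    def test_unparseable(self, label):
        with pytest.raises(FattyAcidParseError):
            parse_fa_name(label)

    def test_out_of_range_carbon(self):
        with pytest.raises(CarbonRangeError):
            parse_fa_name("n-C99")

    @given(
        carbon=st.integers(5, 40),
        branching=st.sampled_from(list(Branching)),
        unsat=st.integers(0, 3),
        oh3=st.booleans(),
    )
    def test_format_parse_round_trip(self, carbon, branching, unsat, oh3):
        desc = FattyAcidDescriptor(carbon, branching, unsat, oh3)
        assert parse_fa_name(format_fa_name(desc)) == desc


class TestMeasurement:
    def test_undetected_has_no_value(self):
        with pytest.raises(ValueError):
            Measurement(oh(15), 1.0, ValueKind.PEAK_AREA, detected=False)

    def test_relative_abundance_bounded(self):
        with pytest.raises(ValueError):
            Measurement(oh(15), 101.0, ValueKind.RELATIVE_ABUNDANCE)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            Measurement(oh(15), -1.0)


def areas(mapping):
    return [
        Measurement(d, v, ValueKind.PEAK_AREA, detected=v is not None)
        if v is not None
        else Measurement(d, None, ValueKind.PEAK_AREA, detected=False)
        for d, v in mapping.items()
    ]


class TestNormalize:
    def test_hand_arithmetic(self):
        x, y, z = oh(13, Branching.ISO), oh(15, Branching.ISO), oh(15)
        prof = normalize(areas({x: 2, y: 3, z: 5}), Basis.TOTAL_3OH_FAS)
        assert prof.detected[x] == pytest.approx(20.0)
        assert prof.detected[y] == pytest.approx(30.0)
        assert prof.detected[z] == pytest.approx(50.0)

    def test_single_compound_is_100(self):
        prof = normalize(areas({oh(14): 7.3}), Basis.TOTAL_3OH_FAS)
        assert prof.detected[oh(14)] == pytest.approx(100.0)

    def test_undetected_preserved(self):
        prof = normalize(areas({oh(14): 2, oh(15): None}), Basis.TOTAL_3OH_FAS)
        assert prof.value_for(oh(15)) is None
        assert not prof.measurements[oh(15)].detected

    def test_degenerate_input(self):
        with pytest.raises(DegenerateInputError):
            normalize([], Basis.TOTAL_3OH_FAS)
        with pytest.raises(DegenerateInputError):
            normalize(areas({oh(14): 0.0}), Basis.TOTAL_3OH_FAS)

    def test_basis_guard(self):
        non_oh = FattyAcidDescriptor(16, Branching.NORMAL, 1, False)
        with pytest.raises(BasisError):
            normalize(areas({non_oh: 5}), Basis.TOTAL_3OH_FAS)

    @given(
        vals=st.lists(
            st.floats(0.01, 1e6, allow_nan=False), min_size=1, max_size=10
        )
    )
    @settings(max_examples=50)
    def test_closure_exact(self, vals):
        descs = [oh(10 + i % 9, Branching.NORMAL if i % 2 else Branching.ISO)
                 for i in range(len(vals))]
        # may collide; dedupe keeping first
        mapping = {}
        for d, v in zip(descs, vals):
            mapping.setdefault(d, v)
        prof = normalize(areas(mapping), Basis.TOTAL_3OH_FAS)
        assert sum(prof.detected.values()) == pytest.approx(100.0, abs=1e-9)

    @given(
        scale=st.floats(1e-3, 1e3),
        vals=st.tuples(st.floats(0.1, 100), st.floats(0.1, 100), st.floats(0.1, 100)),
    )
    @settings(max_examples=50)
    def test_scale_invariance(self, scale, vals):
        descs = (oh(13), oh(14), oh(15))
        base = normalize(areas(dict(zip(descs, vals))), Basis.TOTAL_3OH_FAS)
        scaled = normalize(
            areas({d: v * scale for d, v in zip(descs, vals)}), Basis.TOTAL_3OH_FAS
        )
        for d in descs:
            assert scaled.detected[d] == pytest.approx(base.detected[d], rel=1e-9)

    def test_idempotence(self):
        descs = (oh(13), oh(14), oh(15))
        prof = normalize(areas(dict(zip(descs, (2, 3, 5)))), Basis.TOTAL_3OH_FAS)
        again = normalize(
            [
                Measurement(d, v, ValueKind.PEAK_AREA)
                for d, v in prof.detected.items()
            ],
            Basis.TOTAL_3OH_FAS,
        )
        for d in descs:
            assert again.detected[d] == pytest.approx(prof.detected[d], rel=1e-12)


class TestClassTotals:
    def test_single_normal_homologue(self):
        prof = make_profile({oh(14): 100.0})
        t = class_totals(prof)
        assert (t.iso, t.anteiso, t.normal) == (0.0, 0.0, 100.0)

    def test_table4_strain_a_5c_iso(self, table4):
        agg = table4.aggregate_profile(ConditionVariable.TEMPERATURE_C, 5.0)
        t = class_totals(agg)
        assert t.iso == pytest.approx(80.69, abs=0.02)
        assert t.anteiso == pytest.approx(8.55, abs=0.02)
        assert t.normal == pytest.approx(10.77, abs=0.02)

    def test_out_of_scope_carbon_excluded(self):
        prof = make_profile({oh(14): 50.0, oh(20): 50.0})
        t = class_totals(prof)
        assert t.normal == pytest.approx(50.0)

    def test_non_hydroxy_excluded(self):
        mixed = make_profile(
            {
                FattyAcidDescriptor(16, Branching.NORMAL, 1, False): 60.0,
                FattyAcidDescriptor(15, Branching.ISO, 0, True): 40.0,
            },
            basis=Basis.TOTAL_FAS,
        )
        t = class_totals(mixed)
        assert (t.iso, t.normal) == (pytest.approx(40.0), 0.0)


class TestAggregate:
    def test_hand_mean_sd(self):
        profs = [
            make_profile({oh(15): v}, rep=f"r{i}")
            for i, v in enumerate((5.0, 5.2, 5.4))
        ]
        agg = aggregate_replicates(profs)
        stat = agg.stats[oh(15)]
        assert stat.mean == pytest.approx(5.2)
        assert stat.sd == pytest.approx(0.2)
        assert agg.n_replicates == 3

    def test_single_replicate_sd_undefined(self):
        agg = aggregate_replicates([make_profile({oh(15): 5.0})])
        assert agg.stats[oh(15)].sd is None

    def test_identical_replicates_zero_sd(self):
        profs = [make_profile({oh(15): 60.0, oh(14): 40.0}, rep=f"r{i}") for i in range(3)]
        agg = aggregate_replicates(profs)
        for stat in agg.stats.values():
            assert stat.sd == pytest.approx(0.0)

    def test_undetected_dropped_by_default(self):
        profs = [
            make_profile({oh(15): 4.0}, rep="r1"),
            make_profile({oh(15): None}, rep="r2"),
            make_profile({oh(15): 6.0}, rep="r3"),
        ]
        agg = aggregate_replicates(profs)
        assert agg.stats[oh(15)].mean == pytest.approx(5.0)
        assert agg.stats[oh(15)].n_detected == 2

    def test_zero_imputation_policy(self):
        profs = [
            make_profile({oh(15): 3.0}, rep="r1"),
            make_profile({oh(15): None}, rep="r2"),
            make_profile({oh(15): 6.0}, rep="r3"),
        ]
        agg = aggregate_replicates(profs, zero_impute_undetected=True)
        assert agg.stats[oh(15)].mean == pytest.approx(3.0)

    def test_mixed_bases_rejected(self):
        a = make_profile({oh(15): 100.0})
        b = make_profile(
            {FattyAcidDescriptor(15, Branching.ISO, 0, True): 100.0},
            basis=Basis.TOTAL_FAS,
        )
        with pytest.raises(BasisError):
            aggregate_replicates([a, b])


class TestFixtureConsistency:
    """Printed class totals and closure hold in every fixture column."""

    @pytest.mark.parametrize("name", ["table4", "table5", "table6"])
    @pytest.mark.parametrize(
        "condition", [ConditionVariable.TEMPERATURE_C, ConditionVariable.PH]
    )
    def test_homologue_sums_match_printed_totals(self, oh_tables, name, condition):
        table = oh_tables[name]
        printed = {
            Branching.ISO: "Total iso 3-OH FAs",
            Branching.ANTEISO: "Total anteiso 3-OH FAs",
            Branching.NORMAL: "Total normal 3-OH FAs",
        }
        for level in table.levels(condition):
            agg = table.aggregate_profile(condition, level)
            totals = class_totals(agg)
            for cls, label in printed.items():
                cell = table.cell(label, condition, level)
                assert cell is not None
                got = {
                    Branching.ISO: totals.iso,
                    Branching.ANTEISO: totals.anteiso,
                    Branching.NORMAL: totals.normal,
                }[cls]
                assert got == pytest.approx(cell[0], abs=0.02), (
                    name, condition.value, level, cls.value
                )

    @pytest.mark.parametrize("name", ["table4", "table5", "table6"])
    @pytest.mark.parametrize(
        "condition", [ConditionVariable.TEMPERATURE_C, ConditionVariable.PH]
    )
    def test_column_closure(self, oh_tables, name, condition):
        table = oh_tables[name]
        for level in table.levels(condition):
            agg = table.aggregate_profile(condition, level)
            assert sum(agg.means.values()) == pytest.approx(100.0, abs=0.5), (
                name, condition.value, level
            )
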