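"""Trait-band assignment, cohort loading and trio enumeration."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from famseg.cohort import (
    Diagnosis,
    Family,
    Individual,
    TraitGroup,
    TraitInstrument,
    assign_trait_group,
    enumerate_trios,
    load_cohort,
)
from famseg.exceptions import ConfigError, InputError, PedigreeError

AQ = TraitInstrument("adult-AQ", 20.0, 5.0)


class TestAssignTraitGroup:
    @pytest.mark.parametrize(
        "score,expected",
        [
            (20.0, TraitGroup.AVERAGE),  # at the mean
            (24.9, TraitGroup.AVERAGE),
            (25.0, TraitGroup.BAP),  # lower band edge is closed
            (27.0, TraitGroup.BAP),
            (29.9, TraitGroup.BAP),
            (30.0, TraitGroup.MAP),  # mean + 2 SD belongs to MAP, not BAP
            (34.9, TraitGroup.MAP),
            (35.0, TraitGroup.NAP),
            (50.0, TraitGroup.NAP),
        ],
    )
    def test_band_boundaries(self, score, expected):
        assert assign_trait_group(score, AQ) is expected

    def test_missing_norms_is_config_error(self):
        with pytest.raises(ConfigError):
            assign_trait_group(30.0, None)

    def test_non_finite_score_rejected(self):
        with pytest.raises(InputError):
            assign_trait_group(float("nan"), AQ)

    def test_bad_instrument_rejected(self):
        with pytest.raises(ConfigError):
            TraitInstrument("adult-AQ", 20.0, 0.0)
        with pytest.raises(ConfigError):
            TraitInstrument("other-scale", 20.0, 5.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        a=st.floats(-10, 60, allow_nan=False),
        b=st.floats(-10, 60, allow_nan=False),
    )
    def test_monotone_in_score(self, a, b):
        lo, hi = sorted((a, b))
        assert assign_trait_group(lo, AQ) <= assign_trait_group(hi, AQ)

    @settings(derandomize=True, max_examples=100)
    @given(score=st.floats(-10, 60, allow_nan=False))
    def test_partition(self, score):
        # exactly one band per score
        assert assign_trait_group(score, AQ) in list(TraitGroup)


def _write_cohort(tmp_path, ped_lines, trait_rows):
    ped = tmp_path / "c.ped"
    ped.write_text("".join(line + "\n" for line in ped_lines))
    traits = tmp_path / "t.csv"
    traits.write_text(
        "individual_id,instrument,score\n"
        + "".join(",".join(map(str, r)) + "\n" for r in trait_rows)
    )
    return ped, traits


NORMS = {"adult-AQ": {"mean": 20, "sd": 5}}


class TestLoadCohort:
    def test_family_assembled_with_traits(self, tmp_path):
        ped, traits = _write_cohort(
            tmp_path,
            [
                "FAM1 P1 0 0 1 0 non_autistic",
                "FAM1 P2 0 0 2 0 diagnosed",
                "FAM1 C1 P1 P2 1 0 diagnosed",
                "FAM1 C2 P1 P2 2 0 diagnosed",
                "FAM1 C3 P1 P2 2 0 suspected",
            ],
            [("P1", "adult-AQ", 21), ("P2", "adult-AQ", 38),
             ("C1", "adult-AQ", 36), ("C2", "adult-AQ", 31),
             ("C3", "adult-AQ", 27)],
        )
        fams = load_cohort(ped, traits, NORMS)
        assert set(fams) == {"FAM1"}
        fam = fams["FAM1"]
        assert len(fam.members) == 5
        assert fam.is_highly_multiplex
        assert fam.members["P2"].trait_group is TraitGroup.NAP
        assert fam.members["C2"].trait_group is TraitGroup.MAP
        assert fam.members["C3"].diagnosis is Diagnosis.SUSPECTED

    def test_trait_row_for_unknown_individual(self, tmp_path):
        ped, traits = _write_cohort(
            tmp_path, ["FAM1 P1 0 0 1 0 diagnosed"], [("GHOST", "adult-AQ", 30)]
        )
        with pytest.raises(InputError):
            load_cohort(ped, traits, NORMS)

    def test_duplicate_individual_id(self, tmp_path):
        ped, _ = _write_cohort(
            tmp_path,
            ["FAM1 P1 0 0 1 0 diagnosed", "FAM1 P1 0 0 1 0 diagnosed"],
            [],
        )
        with pytest.raises(InputError):
            load_cohort(ped)

    def test_dangling_parent_reference(self, tmp_path):
        ped, _ = _write_cohort(
            tmp_path, ["FAM1 C1 NOPE MAYBE 1 0 diagnosed"], []
        )
        with pytest.raises(PedigreeError):
            load_cohort(ped)

    def test_plain_six_column_ped_phenotype_coding(self, tmp_path):
        ped = tmp_path / "p.ped"
        ped.write_text("FAM1 A 0 0 1 2\nFAM1 B 0 0 2 1\nFAM1 C A B 1 0\n")
        fams = load_cohort(ped)
        members = fams["FAM1"].members
        assert members["A"].diagnosis is Diagnosis.DIAGNOSED
        assert members["B"].diagnosis is Diagnosis.NON_AUTISTIC
        assert members["C"].diagnosis is Diagnosis.UNKNOWN


def _three_generation_family():
    members = {
        "GF": Individual("GF", "F", sex="male"),
        "GM": Individual("GM", "F", sex="female"),
        "MO": Individual("MO", "F", father_id="GF", mother_id="GM", sex="female"),
        "FA": Individual("FA", "F", sex="male"),
        "C1": Individual("C1", "F", father_id="FA", mother_id="MO"),
        "C2": Individual("C2", "F", father_id="FA", mother_id="MO"),
    }
    return Family(family_id="F", members=members)


class TestEnumerateTrios:
    def test_one_trio_per_genotyped_child(self):
        fam = _three_generation_family()
        ids = set(fam.members)
        trios = enumerate_trios(fam, ids)
        # exhaustive expectation: MO as child of GF/GM, plus C1 and C2
        assert [(t.child.individual_id, t.father.individual_id, t.mother.individual_id)
                for t in trios] == [("C1", "FA", "MO"), ("C2", "FA", "MO"), ("MO", "GF", "GM")]

    def test_ungenotyped_parent_removes_trio(self):
        fam = _three_generation_family()
        trios = enumerate_trios(fam, set(fam.members) - {"FA"})
        assert [t.child.individual_id for t in trios] == ["MO"]

    def test_invariant_under_member_permutation(self):
        fam = _three_generation_family()
        ids = list(fam.members)
        base = enumerate_trios(fam, ids)
        for perm in itertools.permutations(ids, len(ids)):
            fam2 = Family(
                family_id="F", members={i: fam.members[i] for i in perm}
            )
            assert enumerate_trios(fam2, set(perm)) == base
            break  # one non-trivial permutation plus the reversed order below
        rev = {i: fam.members[i] for i in reversed(ids)}
        assert enumerate_trios(Family(family_id="F", members=rev), set(ids)) == base

    def test_pedigree_cycle_rejected(self):
        with pytest.raises(PedigreeError):
            Family(
                family_id="F",
                members={
                    "A": Individual("A", "F", father_id="B"),
                    "B": Individual("B", "F", father_id="A"),
                },
            )
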