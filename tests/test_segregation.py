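"""Within-family segregation rules, checked against a literal brute-force oracle."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from famseg.cohort import Diagnosis, TraitGroup
from famseg.filters import FilterConfig
from famseg.segregation import (
    CarrierSet,
    build_carrier_set,
    diagnosis_segregation,
    prioritise_family,
    summarise_genes,
    trait_segregation,
    PrioritisedVariant,
)
from famseg.variant_io import AnnotatedVariant, GeneConstraint, GenotypeCall, VariantSite

from conftest import make_family

SITE = VariantSite("1", 100, "A", "G")
CFG = FilterConfig()


def carrier_set(family, carriers, weak=frozenset()):
    """Carriers with good support, `weak` carriers failing read support."""
    ids = set(family.members)
    return CarrierSet(
        variant=SITE,
        carriers=frozenset(carriers),
        all_carriers=frozenset(carriers) | frozenset(weak),
        non_carriers=frozenset(ids - set(carriers) - set(weak)),
    )


# ---------------------------------------------------------------------------
# Independent oracle: the prose rules applied literally


def oracle_diagnosis(family, carriers):
    diagnosed_carriers = [
        i for i in carriers if family.members[i].diagnosis is Diagnosis.DIAGNOSED
    ]
    non_autistic_carriers = [
        i for i in carriers if family.members[i].diagnosis is Diagnosis.NON_AUTISTIC
    ]
    return len(diagnosed_carriers) >= 2 and not non_autistic_carriers


def oracle_trait(family, carriers):
    """Most stringent band L such that the variant is present in >= 2 members
    of band L or higher and absent from everyone below band L."""
    groups = [family.members[i].trait_group for i in carriers]
    groups = [g for g in groups if g is not None]
    best = None
    for level in (TraitGroup.BAP, TraitGroup.MAP, TraitGroup.NAP):
        at_or_above = [g for g in groups if g >= level]
        below = [g for g in groups if g < level]
        if len(at_or_above) >= 2 and not below:
            best = level
    return best


DX_VALUES = [
    Diagnosis.DIAGNOSED,
    Diagnosis.NON_AUTISTIC,
    Diagnosis.SUSPECTED,
    Diagnosis.UNKNOWN,
]
GROUPS = list(TraitGroup)


@settings(derandomize=True, max_examples=300)
@given(data=st.data())
def test_oracle_equivalence_exhaustive_small_families(data):
    """On families of <=6 members, every carrier subset agrees with the
    literal prose-rule oracle for both approaches."""
    n = data.draw(st.integers(2, 6))
    specs = [
        (
            f"I{i}",
            data.draw(st.sampled_from(DX_VALUES)),
            data.draw(st.sampled_from(GROUPS)),
        )
        for i in range(n)
    ]
    family = make_family(specs)
    ids = sorted(family.members)
    for r in range(len(ids) + 1):
        for subset in itertools.combinations(ids, r):
            cs = carrier_set(family, subset)
            assert diagnosis_segregation(cs, family) == oracle_diagnosis(
                family, subset
            )
            assert trait_segregation(cs, family) == oracle_trait(family, subset)


class TestDiagnosisSegregation:
    def test_two_diagnosed_carriers_fire(self):
        fam = make_family(
            [("A", Diagnosis.DIAGNOSED, TraitGroup.NAP),
             ("B", Diagnosis.DIAGNOSED, TraitGroup.NAP),
             ("C", Diagnosis.NON_AUTISTIC, TraitGroup.AVERAGE)]
        )
        assert diagnosis_segregation(carrier_set(fam, {"A", "B"}), fam)

    def test_single_diagnosed_carrier_fails_count(self):
        fam = make_family(
            [("A", Diagnosis.DIAGNOSED, TraitGroup.NAP),
             ("B", Diagnosis.DIAGNOSED, TraitGroup.NAP)]
        )
        assert not diagnosis_segregation(carrier_set(fam, {"A"}), fam)

    def test_non_autistic_carrier_vetoes(self):
        fam = make_family(
            [("A", Diagnosis.DIAGNOSED, TraitGroup.NAP),
             ("B", Diagnosis.DIAGNOSED, TraitGroup.NAP),
             ("C", Diagnosis.NON_AUTISTIC, TraitGroup.AVERAGE)]
        )
        assert not diagnosis_segregation(carrier_set(fam, {"A", "B", "C"}), fam)

    def test_weak_support_non_autistic_carrier_still_vetoes(self):
        # the absence rule acts on any non-missing carrier genotype
        fam = make_family(
            [("A", Diagnosis.DIAGNOSED, TraitGroup.NAP),
             ("B", Diagnosis.DIAGNOSED, TraitGroup.NAP),
             ("C", Diagnosis.NON_AUTISTIC, TraitGroup.AVERAGE)]
        )
        assert not diagnosis_segregation(
            carrier_set(fam, {"A", "B"}, weak={"C"}), fam
        )

    def test_suspected_carrier_neither_counts_nor_vetoes(self):
        fam = make_family(
            [("A", Diagnosis.DIAGNOSED, TraitGroup.NAP),
             ("B", Diagnosis.SUSPECTED, TraitGroup.NAP),
             ("C", Diagnosis.DIAGNOSED, TraitGroup.NAP)]
        )
        assert not diagnosis_segregation(carrier_set(fam, {"A", "B"}), fam)
        assert diagnosis_segregation(carrier_set(fam, {"A", "B", "C"}), fam)

    def test_monotone_in_non_autistic_carriers(self):
        fam = make_family(
            [("A", Diagnosis.DIAGNOSED, TraitGroup.NAP),
             ("B", Diagnosis.DIAGNOSED, TraitGroup.NAP),
             ("C", Diagnosis.NON_AUTISTIC, TraitGroup.AVERAGE)]
        )
        with_veto = carrier_set(fam, {"A", "B", "C"})
        without = carrier_set(fam, {"A", "B"})
        # removing a non-autistic carrier can only help, adding only hurt
        assert diagnosis_segregation(without, fam) >= diagnosis_segregation(
            with_veto, fam
        )


class TestTraitSegregation:
    def test_nap_and_map_carriers_give_map(self):
        fam = make_family(
            [("A", Diagnosis.UNKNOWN, TraitGroup.NAP),
             ("B", Diagnosis.UNKNOWN, TraitGroup.MAP)]
        )
        assert trait_segregation(carrier_set(fam, {"A", "B"}), fam) is TraitGroup.MAP

    def test_single_carrier_is_none(self):
        fam = make_family([("A", Diagnosis.UNKNOWN, TraitGroup.NAP)])
        assert trait_segregation(carrier_set(fam, {"A"}), fam) is None

    def test_average_carrier_vetoes(self):
        fam = make_family(
            [("A", Diagnosis.UNKNOWN, TraitGroup.BAP),
             ("B", Diagnosis.UNKNOWN, TraitGroup.AVERAGE)]
        )
        assert trait_segregation(carrier_set(fam, {"A", "B"}), fam) is None

    def test_unscored_carriers_neither_count_nor_veto(self):
        fam = make_family(
            [("A", Diagnosis.UNKNOWN, TraitGroup.NAP),
             ("B", Diagnosis.UNKNOWN, TraitGroup.NAP),
             ("C", Diagnosis.UNKNOWN, None)]
        )
        assert trait_segregation(carrier_set(fam, {"A", "B", "C"}), fam) is TraitGroup.NAP
        assert trait_segregation(carrier_set(fam, {"A", "C"}), fam) is None

    def test_invariant_under_raising_non_minimum_carrier(self):
        lo = make_family(
            [("A", Diagnosis.UNKNOWN, TraitGroup.MAP),
             ("B", Diagnosis.UNKNOWN, TraitGroup.MAP)]
        )
        hi = make_family(
            [("A", Diagnosis.UNKNOWN, TraitGroup.MAP),
             ("B", Diagnosis.UNKNOWN, TraitGroup.NAP)]
        )
        assert (
            trait_segregation(carrier_set(lo, {"A", "B"}), lo)
            == trait_segregation(carrier_set(hi, {"A", "B"}), hi)
            == TraitGroup.MAP
        )


class TestPrioritiseFamily:
    def _inputs(self, carrier_calls):
        av = AnnotatedVariant(
            site=SITE, gene="G1", func_class="stopgain", maf_nfe=0.001
        )
        constraints = {"G1": GeneConstraint("G1", pli=0.99)}
        return [(av, carrier_calls)], constraints

    def test_planted_diagnosis_variant_recovered(self):
        fam = make_family(
            [("A", Diagnosis.DIAGNOSED, TraitGroup.NAP),
             ("B", Diagnosis.DIAGNOSED, TraitGroup.NAP),
             ("C", Diagnosis.DIAGNOSED, TraitGroup.MAP),
             ("D", Diagnosis.NON_AUTISTIC, TraitGroup.AVERAGE)]
        )
        calls = {
            "A": GenotypeCall("A", "het", 30, 15),
            "B": GenotypeCall("B", "het", 30, 15),
            "C": GenotypeCall("C", "het", 30, 15),
            "D": GenotypeCall("D", "hom_ref", 30, 0),
        }
        variants, constraints = self._inputs(calls)
        out = prioritise_family(fam, variants, constraints, CFG, mode="both")
        assert len(out) == 1
        assert out[0].diagnosis_hit and out[0].trait_level is TraitGroup.MAP
        assert out[0].carriers == {"A", "B", "C"}

    def test_non_autistic_carrier_empties_result(self):
        fam = make_family(
            [("A", Diagnosis.DIAGNOSED, TraitGroup.NAP),
             ("B", Diagnosis.DIAGNOSED, TraitGroup.NAP),
             ("D", Diagnosis.NON_AUTISTIC, TraitGroup.AVERAGE)]
        )
        calls = {i: GenotypeCall(i, "het", 30, 15) for i in "ABD"}
        variants, constraints = self._inputs(calls)
        assert prioritise_family(fam, variants, constraints, CFG, mode="diagnosis") == []

    def test_unconstrained_gene_filtered(self):
        fam = make_family(
            [("A", Diagnosis.DIAGNOSED, TraitGroup.NAP),
             ("B", Diagnosis.DIAGNOSED, TraitGroup.NAP)]
        )
        calls = {i: GenotypeCall(i, "het", 30, 15) for i in "AB"}
        variants, _ = self._inputs(calls)
        constraints = {"G1": GeneConstraint("G1", pli=0.1, loeuf=1.0)}
        assert prioritise_family(fam, variants, constraints, CFG) == []

    def test_per_family_independence(self):
        """Cohort output is the concatenation of per-family outputs."""
        fam1 = make_family(
            [("A", Diagnosis.DIAGNOSED, TraitGroup.NAP),
             ("B", Diagnosis.DIAGNOSED, TraitGroup.NAP)],
            fam="X",
        )
        fam2 = make_family(
            [("C", Diagnosis.DIAGNOSED, TraitGroup.NAP),
             ("D", Diagnosis.DIAGNOSED, TraitGroup.NAP)],
            fam="Y",
        )
        calls = {i: GenotypeCall(i, "het", 30, 15) for i in "ABCD"}
        variants, constraints = self._inputs(calls)
        separate = prioritise_family(fam1, variants, constraints, CFG) + prioritise_family(
            fam2, variants, constraints, CFG
        )
        reverse = prioritise_family(fam2, variants, constraints, CFG) + prioritise_family(
            fam1, variants, constraints, CFG
        )
        assert {(pv.family_id, pv.variant.site.key) for pv in separate} == {
            (pv.family_id, pv.variant.site.key) for pv in reverse
        }
        assert len(separate) == 2


class TestSummariseGenes:
    def _pv(self, gene, fam, dx, level, origin="inherited"):
        av = AnnotatedVariant(site=SITE, gene=gene, func_class="stopgain")
        return PrioritisedVariant(
            variant=av, family_id=fam, diagnosis_hit=dx, trait_level=level,
            origin=origin,
        )

    def test_empty(self):
        summaries, venn = summarise_genes([])
        assert summaries == [] and venn == {"both": 0, "trait_only": 0, "diagnosis_only": 0}

    def test_cross_family_both_classification(self):
        # gene A: trait-only in one family, diagnosis-only in another -> both
        pvs = [
            self._pv("A", "f1", False, TraitGroup.NAP),
            self._pv("A", "f2", True, None),
            self._pv("B", "f1", True, None),
            self._pv("C", "f3", False, TraitGroup.BAP),
        ]
        summaries, venn = summarise_genes(pvs)
        assert venn == {"both": 1, "trait_only": 1, "diagnosis_only": 1}
        a = next(s for s in summaries if s.gene == "A")
        assert a.approaches == "both"
        assert a.families == ("f1", "f2")
        assert a.best_trait_level is TraitGroup.NAP

    def test_multi_family_gene_counted_once(self):
        pvs = [
            self._pv("A", "f1", True, TraitGroup.NAP),
            self._pv("A", "f2", True, TraitGroup.MAP),
        ]
        summaries, venn = summarise_genes(pvs)
        assert len(summaries) == 1
        assert venn["both"] == 1
        assert summaries[0].trait_levels == {TraitGroup.NAP, TraitGroup.MAP}
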