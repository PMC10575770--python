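"""Trio de novo filter gates and scanning."""

import pytest

from famseg.cohort import Diagnosis, TraitGroup
from famseg.denovo import (
    DeNovoConfig,
    TrioSiteEvidence,
    candidate_to_prioritised,
    is_de_novo_candidate,
    scan_trios,
)
from famseg.cohort import Trio
from famseg.variant_io import AnnotatedVariant, GeneConstraint, GenotypeCall, VariantSite

from conftest import make_individual

SITE = VariantSite("2", 500, "C", "T")
CONSTRAINTS = {"G1": GeneConstraint("G1", pli=0.95, loeuf=0.2)}
CFG = DeNovoConfig()


def make_trio(child_dx=Diagnosis.DIAGNOSED, child_group=TraitGroup.BAP):
    father = make_individual("FA", dx=Diagnosis.NON_AUTISTIC, group=TraitGroup.AVERAGE)
    mother = make_individual("MO", dx=Diagnosis.DIAGNOSED, group=TraitGroup.NAP)
    child = make_individual("CH", dx=child_dx, group=child_group,
                            father="FA", mother="MO")
    return Trio(father=father, mother=mother, child=child)


def evidence(child=(25, 11), father=(25, 0), mother=(25, 0),
             variant=None, child_gt="het"):
    return TrioSiteEvidence(
        trio=make_trio(),
        variant=variant
        or AnnotatedVariant(site=SITE, gene="G1", func_class="stopgain"),
        child_depth=child[0], child_alt=child[1],
        father_depth=father[0], father_alt=father[1],
        mother_depth=mother[0], mother_alt=mother[1],
        child_gt=child_gt,
    )


class TestGates:
    def test_all_gates_satisfied(self):
        assert is_de_novo_candidate(evidence(), CONSTRAINTS, CFG)

    def test_depth_20_is_strictly_insufficient(self):
        assert not is_de_novo_candidate(evidence(child=(20, 11)), CONSTRAINTS, CFG)
        assert not is_de_novo_candidate(evidence(father=(20, 0)), CONSTRAINTS, CFG)

    def test_child_alt_count_and_fraction_both_required(self):
        # alt count passes (8 >= 8) but fraction 0.32 <= 0.40
        assert not is_de_novo_candidate(evidence(child=(25, 8)), CONSTRAINTS, CFG)
        # fraction passes but count fails: 7/16 = 0.44
        e = evidence(child=(22, 7))
        assert not is_de_novo_candidate(e, CONSTRAINTS, CFG)

    @pytest.mark.parametrize("depth", [21, 22, 25, 30, 40])
    def test_pass_region_exhaustive_over_child_alt(self, depth):
        """For each depth, the passing alt counts are exactly
        {a : a >= 8 and a/depth > 0.40} — verified by full enumeration."""
        passing = {
            alt
            for alt in range(depth + 1)
            if is_de_novo_candidate(evidence(child=(depth, alt)), CONSTRAINTS, CFG)
        }
        expected = {a for a in range(depth + 1) if a >= 8 and a / depth > 0.40}
        assert passing == expected

    def test_parent_alt_fraction_vetoes_per_parent(self):
        assert not is_de_novo_candidate(evidence(father=(100, 6)), CONSTRAINTS, CFG)
        assert not is_de_novo_candidate(evidence(mother=(100, 6)), CONSTRAINTS, CFG)
        assert is_de_novo_candidate(evidence(father=(100, 4), mother=(100, 4)),
                                    CONSTRAINTS, CFG)

    def test_father_mother_symmetry(self):
        e1 = evidence(father=(30, 2), mother=(50, 1))
        e2 = evidence(father=(50, 1), mother=(30, 2))
        assert is_de_novo_candidate(e1, CONSTRAINTS, CFG) == is_de_novo_candidate(
            e2, CONSTRAINTS, CFG
        )

    def test_maf_gate_is_inclusive_at_one_percent(self):
        v = AnnotatedVariant(site=SITE, gene="G1", func_class="stopgain", maf_nfe=0.01)
        assert is_de_novo_candidate(evidence(variant=v), CONSTRAINTS, CFG)
        v2 = AnnotatedVariant(site=SITE, gene="G1", func_class="stopgain", maf_nfe=0.011)
        assert not is_de_novo_candidate(evidence(variant=v2), CONSTRAINTS, CFG)

    def test_splicing_qualifies_in_de_novo_branch(self):
        v = AnnotatedVariant(site=SITE, gene="G1", func_class="splicing")
        assert is_de_novo_candidate(evidence(variant=v), CONSTRAINTS, CFG)

    def test_missense_requires_predictors(self):
        v = AnnotatedVariant(site=SITE, gene="G1", func_class="nonsynonymous_snv",
                             sift="D", polyphen_hdiv="P")
        assert is_de_novo_candidate(evidence(variant=v), CONSTRAINTS, CFG)
        v2 = AnnotatedVariant(site=SITE, gene="G1", func_class="nonsynonymous_snv",
                              sift="T", polyphen_hdiv="D")
        assert not is_de_novo_candidate(evidence(variant=v2), CONSTRAINTS, CFG)

    def test_pli_gate_and_absent_gene(self):
        low = {"G1": GeneConstraint("G1", pli=0.5)}
        assert not is_de_novo_candidate(evidence(), low, CFG)
        assert not is_de_novo_candidate(evidence(), {}, CFG)

    def test_non_het_child_genotype_rejected(self):
        assert not is_de_novo_candidate(evidence(child_gt="hom_alt"), CONSTRAINTS, CFG)

    def test_missing_evidence_fails_closed(self):
        e = TrioSiteEvidence(
            trio=make_trio(),
            variant=AnnotatedVariant(site=SITE, gene="G1", func_class="stopgain"),
            child_depth=None, child_alt=None,
            father_depth=25, father_alt=0, mother_depth=25, mother_alt=0,
        )
        assert not is_de_novo_candidate(e, CONSTRAINTS, CFG)


class TestScanTrios:
    def _variants(self):
        av = AnnotatedVariant(site=SITE, gene="G1", func_class="stopgain")
        calls = {
            "CH": GenotypeCall("CH", "het", 25, 11),
            "FA": GenotypeCall("FA", "hom_ref", 25, 0),
            "MO": GenotypeCall("MO", "hom_ref", 25, 0),
        }
        return [(av, calls)]

    def test_planted_de_novo_recovered(self):
        trio = make_trio()
        out = scan_trios([trio], self._variants(), CONSTRAINTS, CFG)
        assert len(out) == 1
        assert out[0].gene == "G1" and out[0].pli == 0.95

    def test_parental_signal_rejects(self):
        av, calls = self._variants()[0]
        calls = dict(calls)
        calls["FA"] = GenotypeCall("FA", "hom_ref", 50, 3)  # 6% alt
        assert scan_trios([make_trio()], [(av, calls)], CONSTRAINTS, CFG) == []

    def test_trio_member_missing_from_calls_skipped(self):
        av, calls = self._variants()[0]
        calls = {k: v for k, v in calls.items() if k != "MO"}
        assert scan_trios([make_trio()], [(av, calls)], CONSTRAINTS, CFG) == []


class TestCandidateLabelling:
    def test_diagnosed_elevated_child(self):
        trio = make_trio(child_dx=Diagnosis.DIAGNOSED, child_group=TraitGroup.BAP)
        cand = scan_trios([trio], TestScanTrios()._variants(), CONSTRAINTS, CFG)[0]
        pv = candidate_to_prioritised(cand)
        assert pv.origin == "de_novo"
        assert pv.label == "BAP/Diagnosis"
        assert pv.carriers == {"CH"}

    def test_diagnosed_average_child_is_diagnosis_only(self):
        trio = make_trio(child_dx=Diagnosis.DIAGNOSED, child_group=TraitGroup.AVERAGE)
        cand = scan_trios([trio], TestScanTrios()._variants(), CONSTRAINTS, CFG)[0]
        assert candidate_to_prioritised(cand).label == "Diagnosis"

    def test_unlabelled_child_yields_none(self):
        trio = make_trio(child_dx=Diagnosis.NON_AUTISTIC, child_group=TraitGroup.AVERAGE)
        cand = scan_trios([trio], TestScanTrios()._variants(), CONSTRAINTS, CFG)[0]
        assert candidate_to_prioritised(cand) is None
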