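"""Within-family segregation filters and cross-family gene summaries.

Two complementary prioritisation approaches run over the same post-filter
variant set in each family:

* diagnosis-based — a variant must be shared by at least two diagnosed
  members and absent from every strictly non-autistic member (suspected
  and unknown-status members neither count toward the two nor veto);
* trait-based — a variant is labelled with the lowest trait subgroup among
  its carriers, provided at least two scored carriers exist and none falls
  below the broad-autistic-phenotype band.  A NAP label therefore means
  "carried only by NAP members", a MAP label "only MAP and NAP", and so on.

Across families, genes are classified by which approach implicated them
(both / trait-only / diagnosis-only), the comparison the study's Venn
diagram summarises.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .cohort import Diagnosis, Family, TraitGroup
from .filters import FilterConfig, is_constrained, is_rare_damaging, passes_read_support
from .variant_io import (
    AnnotatedVariant,
    GeneConstraint,
    GenotypeCall,
    ReportRow,
    VariantSite,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CarrierSet:
    """Carrier/non-carrier partition of one family at one site.

    ``carriers`` holds alt-carrying members whose call passes read support;
    ``all_carriers`` additionally includes alt carriers with weak support
    (used for the absence veto); members with missing genotypes belong to
    neither set.
    """

    variant: VariantSite
    carriers: frozenset[str]
    all_carriers: frozenset[str]
    non_carriers: frozenset[str]

    def __post_init__(self) -> None:
        assert not (self.all_carriers & self.non_carriers)
        assert self.carriers <= self.all_carriers


def build_carrier_set(
    site: VariantSite,
    calls: Mapping[str, GenotypeCall],
    family: Family,
    cfg: FilterConfig,
) -> CarrierSet:
    carriers, all_carriers, non_carriers = set(), set(), set()
    for iid in family.members:
        call = calls.get(iid)
        if call is None or call.gt == "missing":
            continue
        if call.carries_alt:
            all_carriers.add(iid)
            if passes_read_support(call, cfg):
                carriers.add(iid)
        else:
            non_carriers.add(iid)
    return CarrierSet(
        variant=site,
        carriers=frozenset(carriers),
        all_carriers=frozenset(all_carriers),
        non_carriers=frozenset(non_carriers),
    )


def diagnosis_segregation(cs: CarrierSet, family: Family) -> bool:
    """Shared by ≥2 diagnosed members and absent from all non-autistic ones.

    The veto acts on any non-missing carrier genotype, read support aside;
    suspected/unknown members may carry without vetoing.
    """
    if len(cs.carriers & family.diagnosed) < 2:
        return False
    return not (cs.all_carriers & family.non_autistic)


def trait_segregation(cs: CarrierSet, family: Family) -> TraitGroup | None:
    """Trait-subgroup label of the variant, or None if it does not segregate.

    The label is the minimum trait group over scored, support-passing
    carriers; at least two such carriers are required and any carrier in
    the AVERAGE band vetoes.  Unscored carriers neither count nor veto.
    """
    groups = []
    for iid in cs.carriers:
        g = family.members[iid].trait_group
        if g is None:
            log.debug("unscored carrier %s ignored in trait segregation", iid)
            continue
        groups.append(g)
    if len(groups) < 2:
        return None
    level = min(groups)
    return None if level == TraitGroup.AVERAGE else level


@dataclass(frozen=True)
class PrioritisedVariant:
    variant: AnnotatedVariant
    family_id: str
    diagnosis_hit: bool
    trait_level: TraitGroup | None  # None = not trait-labelled
    origin: str = "inherited"  # inherited / de_novo
    carriers: frozenset[str] = frozenset()
    tier: int | None = None

    def __post_init__(self) -> None:
        assert self.diagnosis_hit or self.trait_level is not None

    @property
    def label(self) -> str:
        parts = []
        if self.trait_level is not None:
            parts.append(self.trait_level.name)
        if self.diagnosis_hit:
            parts.append("Diagnosis")
        return "/".join(parts)

    def to_report_row(self) -> ReportRow:
        s = self.variant.site
        return ReportRow(
            gene=self.variant.gene,
            origin=self.origin,
            family=self.family_id,
            label=self.label,
            chrom_pos=f"{s.chrom}:{s.pos}",
            ref_alt=f"{s.ref}/{s.alt}",
            aa_change=self.variant.aa_change,
            dbsnp=self.variant.dbsnp,
            maf_nfe=self.variant.maf_nfe,
            sift=self.variant.sift,
            polyphen_hdiv=self.variant.polyphen_hdiv,
            tier=self.tier,
            carriers=tuple(sorted(self.carriers)),
        )


def prioritise_family(
    family: Family,
    variants: Iterable[tuple[AnnotatedVariant, Mapping[str, GenotypeCall]]],
    constraints: Mapping[str, GeneConstraint],
    cfg: FilterConfig,
    mode: str = "both",
) -> list[PrioritisedVariant]:
    """Run the site filters and the selected segregation approach(es).

    ``variants`` streams annotated sites with per-individual genotype calls
    (only this family's members are consulted).  Families are processed
    independently; the cohort-level result is the concatenation of
    per-family results.
    """
    if mode not in ("diagnosis", "trait", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode in ("diagnosis", "both") and len(family.diagnosed) < 2:
        log.warning(
            "family %s: <2 diagnosed members; diagnosis approach cannot fire",
            family.family_id,
        )
    out: list[PrioritisedVariant] = []
    for av, calls in variants:
        if not is_rare_damaging(av, cfg):
            continue
        if not is_constrained(constraints.get(av.gene), cfg):
            continue
        cs = build_carrier_set(av.site, calls, family, cfg)
        dx_hit = mode in ("diagnosis", "both") and diagnosis_segregation(cs, family)
        level = trait_segregation(cs, family) if mode in ("trait", "both") else None
        if dx_hit or level is not None:
            out.append(
                PrioritisedVariant(
                    variant=av,
                    family_id=family.family_id,
                    diagnosis_hit=dx_hit,
                    trait_level=level,
                    origin="inherited",
                    carriers=cs.carriers,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Cross-family gene summaries


@dataclass(frozen=True)
class GeneSummary:
    gene: str
    families: tuple[str, ...]
    approaches: str  # trait_only / diagnosis_only / both
    best_trait_level: TraitGroup | None
    trait_levels: frozenset[TraitGroup]
    tier: int | None = None


def summarise_genes(
    prioritised: Iterable[PrioritisedVariant],
    tiers: Mapping[str, int | None] | None = None,
) -> tuple[list[GeneSummary], dict[str, int]]:
    """One summary per distinct gene, plus the approach Venn counts.

    A gene hit in several families yields a single summary listing them
    all; the Venn counts distinct genes once.  ``approaches`` is ``both``
    iff the gene has at least one trait-labelled and at least one
    diagnosis-labelled prioritised variant across all families.
    """
    by_gene: dict[str, list[PrioritisedVariant]] = {}
    for pv in prioritised:
        by_gene.setdefault(pv.variant.gene, []).append(pv)

    summaries: list[GeneSummary] = []
    venn = {"both": 0, "trait_only": 0, "diagnosis_only": 0}
    for gene in sorted(by_gene):
        pvs = by_gene[gene]
        has_trait = any(pv.trait_level is not None for pv in pvs)
        has_dx = any(pv.diagnosis_hit for pv in pvs)
        approaches = (
            "both" if has_trait and has_dx else "trait_only" if has_trait else "diagnosis_only"
        )
        venn[approaches] += 1
        levels = frozenset(
            pv.trait_level for pv in pvs if pv.trait_level is not None
        )
        summaries.append(
            GeneSummary(
                gene=gene,
                families=tuple(sorted({pv.family_id for pv in pvs})),
                approaches=approaches,
                best_trait_level=max(levels) if levels else None,
                trait_levels=levels,
                tier=None if tiers is None else tiers.get(gene),
            )
        )
    return summaries, venn
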