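"""Trio de novo variant filter.

Candidates are evaluated per trio over jointly represented genotypes with
five gates: read depth strictly above 20 in child and both parents; at
least 8 alternate reads in the child; a heterozygous child signal with alt
fraction above 40% while each parent's alt fraction stays below 5%; gnomAD
NFE frequency at or below 1% (or absent); and a disruptive functional class
(missense deleterious by SIFT with PolyPhen-2 HDIV at least possibly
damaging, frameshift indel, stop gain/loss, or splice junction).  Passing
variants are retained only in genes with pLI ≥ 0.9.

Upstream trio variant calling (e.g. a caller's trio mode with loose
coverage/frequency settings) is assumed strictly more permissive than these
gates, so applying them to any jointly genotyped trio sites reproduces the
filter's intent regardless of caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .cohort import Diagnosis, Trio
from .segregation import PrioritisedVariant
from .variant_io import AnnotatedVariant, GeneConstraint, GenotypeCall, HET, MISSING
from .exceptions import ConfigError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeNovoConfig:
    min_depth_exclusive: int = 20  # depth must be strictly greater
    min_child_alt_reads: int = 8
    min_child_alt_fraction: float = 0.40  # strictly greater
    max_parent_alt_fraction: float = 0.05  # strictly less
    maf_threshold: float = 0.01
    maf_inclusive: bool = True  # de novo branch uses "<= 1%"
    pli_threshold: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_threshold <= 1.0):
            raise ConfigError("maf_threshold must be in [0, 1]")
        if not (0.0 <= self.pli_threshold <= 1.0):
            raise ConfigError("pli_threshold must be in [0, 1]")


#: Disruptive classes in the de novo branch (splicing qualifies here).
DENOVO_CLASSES = frozenset(
    {
        "stopgain",
        "stoploss",
        "frameshift_insertion",
        "frameshift_deletion",
        "splicing",
    }
)


@dataclass(frozen=True)
class TrioSiteEvidence:
    trio: Trio
    variant: AnnotatedVariant
    child_depth: int | None
    father_depth: int | None
    mother_depth: int | None
    child_alt: int | None
    father_alt: int | None
    mother_alt: int | None
    child_gt: str = MISSING

    def __post_init__(self) -> None:
        for who in ("child", "father", "mother"):
            d = getattr(self, f"{who}_depth")
            a = getattr(self, f"{who}_alt")
            if d is not None and a is not None and not (0 <= a <= d):
                raise ValueError(f"{who}: alt {a} outside [0, depth={d}]")


@dataclass(frozen=True)
class DeNovoCandidate:
    evidence: TrioSiteEvidence
    gene: str
    pli: float


def _func_qualifies(v: AnnotatedVariant) -> bool:
    if v.func_class in DENOVO_CLASSES:
        return True
    if v.func_class == "nonsynonymous_snv":
        return v.sift == "D" and v.polyphen_hdiv in ("D", "P")
    return False


def is_de_novo_candidate(
    e: TrioSiteEvidence,
    constraints: Mapping[str, GeneConstraint],
    cfg: DeNovoConfig = DeNovoConfig(),
) -> bool:
    """Apply all de novo gates to one trio-site; missing evidence fails closed."""
    depths = (e.child_depth, e.father_depth, e.mother_depth)
    alts = (e.child_alt, e.father_alt, e.mother_alt)
    if any(d is None for d in depths) or any(a is None for a in alts):
        return False
    if not all(d > cfg.min_depth_exclusive for d in depths):
        return False
    if e.child_alt < cfg.min_child_alt_reads:
        return False
    # child heterozygosity: trust the genotype call when present, else the
    # alt-fraction window (no upper bound is imposed)
    if e.child_gt not in (HET, MISSING):
        return False
    if not (e.child_alt / e.child_depth > cfg.min_child_alt_fraction):
        return False
    # "absent in parents" is per-parent, not pooled
    if not (e.father_alt / e.father_depth < cfg.max_parent_alt_fraction):
        return False
    if not (e.mother_alt / e.mother_depth < cfg.max_parent_alt_fraction):
        return False
    maf = e.variant.maf_nfe
    if maf is not None:
        rare = maf <= cfg.maf_threshold if cfg.maf_inclusive else maf < cfg.maf_threshold
        if not rare:
            return False
    if not _func_qualifies(e.variant):
        return False
    gc = constraints.get(e.variant.gene)
    if gc is None or gc.pli is None or gc.pli < cfg.pli_threshold:
        if gc is None:
            log.debug("gene %s absent from constraint map: fails pLI gate", e.variant.gene)
        return False
    return True


def scan_trios(
    trios: Sequence[Trio],
    variants: Iterable[tuple[AnnotatedVariant, Mapping[str, GenotypeCall]]],
    constraints: Mapping[str, GeneConstraint],
    cfg: DeNovoConfig = DeNovoConfig(),
) -> list[DeNovoCandidate]:
    """Evaluate every trio at every site; deterministic (child, chrom, pos) order."""
    variants = list(variants)
    candidates: list[DeNovoCandidate] = []
    for trio in sorted(trios, key=lambda t: t.child.individual_id):
        ids = {
            trio.child.individual_id,
            trio.father.individual_id,
            trio.mother.individual_id,
        }
        for av, calls in variants:
            if not ids <= set(calls):
                log.warning(
                    "trio (child %s) member missing from genotypes at %s:%d: skipped",
                    trio.child.individual_id,
                    av.site.chrom,
                    av.site.pos,
                )
                continue
            c = calls[trio.child.individual_id]
            f = calls[trio.father.individual_id]
            m = calls[trio.mother.individual_id]
            e = TrioSiteEvidence(
                trio=trio,
                variant=av,
                child_depth=c.depth,
                father_depth=f.depth,
                mother_depth=m.depth,
                child_alt=c.alt_reads,
                father_alt=f.alt_reads,
                mother_alt=m.alt_reads,
                child_gt=c.gt,
            )
            if is_de_novo_candidate(e, constraints, cfg):
                candidates.append(
                    DeNovoCandidate(
                        evidence=e,
                        gene=av.gene,
                        pli=constraints[av.gene].pli,
                    )
                )
    candidates.sort(
        key=lambda c: (
            c.evidence.trio.child.individual_id,
            c.evidence.variant.site.chrom,
            c.evidence.variant.site.pos,
        )
    )
    return candidates


def candidate_to_prioritised(c: DeNovoCandidate) -> PrioritisedVariant | None:
    """Label a de novo candidate by its carrier child.

    The child's diagnosis and trait subgroup supply the combined
    trait/diagnosis label, mirroring how de novo hits enter the cross-family
    approach comparison.  Returns None when the child is neither diagnosed
    nor in an elevated trait band (the candidate then carries no label).
    """
    from .cohort import TraitGroup

    child = c.evidence.trio.child
    level = child.trait_group
    trait_level = level if level is not None and level > TraitGroup.AVERAGE else None
    if trait_level is None and child.diagnosis is not Diagnosis.DIAGNOSED:
        return None
    return PrioritisedVariant(
        variant=c.evidence.variant,
        family_id=child.family_id,
        diagnosis_hit=child.diagnosis is Diagnosis.DIAGNOSED,
        trait_level=trait_level,
        origin="de_novo",
        carriers=frozenset({child.individual_id}),
    )
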