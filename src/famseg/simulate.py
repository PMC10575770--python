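"""Synthetic multiplex-cohort generator.

Emits a complete analysis-ready bundle — multi-sample VCF, diagnosis-
extended PED, trait table, instrument norms, annotation and constraint
tables, tier source lists and a truth table — with the statistical
structure the pipeline assumes:

* families ascertained for ≥3 diagnosed members (with optionally one
  under-recruited family carrying only two, mirroring real cohorts);
* trait scores drawn from diagnosis-dependent normal models on the
  instrument scale, so diagnosed members concentrate in the MAP/NAP bands
  and their relatives sit modestly above the population mean;
* planted diagnosis-segregating and trait-segregating variants placed
  heterozygous on a founder and transmitted by honest Mendelian sampling
  (one allele per meiosis at probability ½), rejection-sampled until the
  carrier pattern satisfies the target rule — plants are never painted
  directly onto phenotypes;
* planted de novo variants in one child of a genotyped trio with
  hom-ref parents and read evidence inside the de novo filter's
  acceptance region;
* background noise variants with random founder placement, honest
  transmission, an optional genotype-error rate, and annotations that
  pass the damaging/constraint filters only at a configurable rate;
* per-call read evidence: depth ~ Poisson(λ), alt reads ~ Binomial(depth,
  f) with f ≈ ½ for heterozygotes and a small error fraction otherwise.

The same seed always yields a byte-identical bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
import yaml

from .cohort import Diagnosis, Family, Individual, TraitGroup, TraitInstrument
from .exceptions import SimulationError
from .variant_io import HET, HOM_ALT, HOM_REF

_GT_STATES = (HOM_REF, HET, HOM_ALT)


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults emulate the 21-family study shape."""

    n_families: int = 21
    children_range: tuple[int, int] = (3, 4)  # inclusive; +2 parents
    generations: int = 2
    p_child_diagnosed: float = 0.55
    min_diagnosed_per_family: int = 3
    n_small_families: int = 1  # families capped at 2 diagnosed members
    n_suspected: int = 4
    instrument_name: str = "adult-AQ"
    norm_mean: float = 20.0
    norm_sd: float = 5.0
    score_min: float = 0.0
    score_max: float = 50.0
    k_dx: float = 2.6  # diagnosed trait offset, in norm SD units
    sd_dx: float = 0.9  # diagnosed trait spread, in norm SD units
    k_bg: float = 0.6  # non-diagnosed relatives' offset
    sd_bg: float = 1.0
    n_planted_diagnosis_per_family: int = 1
    n_planted_trait_per_family: int = 1
    n_planted_denovo: int = 6
    n_noise_variants: int = 100
    noise_annotation_pass_rate: float = 0.0
    depth_lambda: float = 35.0
    base_error_alt_fraction: float = 0.005
    genotype_error_rate: float = 0.0
    max_plant_retries: int = 5000
    seed: int = 0
    #: optional explicit per-family plan (n_children, n_diagnosed); overrides
    #: children_range / p_child_diagnosed / n_small_families when set
    family_plan: tuple[tuple[int, int], ...] | None = None

    @property
    def instrument(self) -> TraitInstrument:
        return TraitInstrument(self.instrument_name, self.norm_mean, self.norm_sd)


#: Exact cohort shape of the motivating 21-family study: 112 members, 76
#: diagnosed, ten families with ≥4 diagnosed, one under-recruited family
#: (tenth) with only two diagnosed members genotyped.
STUDY_PLAN: tuple[tuple[int, int], ...] = (
    (4, 5), (4, 5), (4, 5), (4, 5), (4, 4), (4, 4), (4, 4),
    (3, 4), (3, 4), (3, 2), (3, 4),
    (3, 3), (3, 3), (3, 3), (3, 3), (3, 3),
    (3, 3), (3, 3), (3, 3), (3, 3), (3, 3),
)


def study_config(**overrides) -> SimConfig:
    """A generator config reproducing the study's participant counts."""
    return SimConfig(family_plan=STUDY_PLAN, **overrides)


@dataclass(frozen=True)
class PlantedVariant:
    """Truth-table entry for one generated site."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    family_id: str | None
    category: str  # diagnosis / trait / de_novo / noise
    trait_level: str | None
    carriers: tuple[str, ...]

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SimResult:
    config: SimConfig
    families: dict[str, Family]
    truth: list[PlantedVariant]
    paths: dict[str, Path]
    #: analytic expectation/variance of Mendelian-violation counts at noise
    #: sites under the configured genotype-error rate (sum over trio-sites of
    #: per-trio violation probabilities; independence approximation)
    expected_noise_violations: float = 0.0
    noise_violation_variance: float = 0.0


# ---------------------------------------------------------------------------
# Pedigree and phenotype construction


def _build_family(
    fid: str, n_children: int, generations: int, rng: np.random.Generator
) -> dict[str, Individual]:
    members: dict[str, Individual] = {}
    father, mother = f"{fid}_F", f"{fid}_M"
    if generations == 3:
        gf, gm = f"{fid}_GF", f"{fid}_GM"
        members[gf] = Individual(gf, fid, sex="male")
        members[gm] = Individual(gm, fid, sex="female")
        # mother is herself a child of the genotyped grandparents
        members[mother] = Individual(
            mother, fid, father_id=gf, mother_id=gm, sex="female"
        )
        members[father] = Individual(father, fid, sex="male")
    else:
        members[father] = Individual(father, fid, sex="male")
        members[mother] = Individual(mother, fid, sex="female")
    for i in range(n_children):
        cid = f"{fid}_C{i + 1}"
        members[cid] = Individual(
            cid,
            fid,
            father_id=father,
            mother_id=mother,
            sex="female" if rng.random() < 0.5 else "male",
        )
    return members


def _assign_phenotypes(
    members: dict[str, Individual],
    fid: str,
    small: bool,
    cfg: SimConfig,
    rng: np.random.Generator,
    n_diagnosed: int | None = None,
) -> None:
    mother = f"{fid}_M"
    if n_diagnosed is not None:
        # explicit plan: the mother plus the first children, deterministically
        children = sorted(i for i in members if members[i].father_id is not None)
        chosen = {mother} | set(children[: n_diagnosed - 1])
        for iid, ind in members.items():
            ind.diagnosis = (
                Diagnosis.DIAGNOSED if iid in chosen else Diagnosis.NON_AUTISTIC
            )
        return
    # ascertainment anchors: the mother, plus a diagnosed founder grandmother
    # in three-generation families (plants need a diagnosed founder carrier)
    anchors = {mother} | ({f"{fid}_GM"} & set(members))
    child_ids = [i for i in members if members[i].father_id is not None]
    for iid, ind in members.items():
        if iid in anchors:
            ind.diagnosis = Diagnosis.DIAGNOSED
        elif iid in child_ids and rng.random() < cfg.p_child_diagnosed:
            ind.diagnosis = Diagnosis.DIAGNOSED
        else:
            ind.diagnosis = Diagnosis.NON_AUTISTIC
    diagnosed = [i for i, m in members.items() if m.diagnosis is Diagnosis.DIAGNOSED]
    if small:
        # under-recruited family: keep the anchors plus one diagnosed child
        keep = set(anchors)
        extra = [i for i in diagnosed if i not in anchors]
        if not extra:
            extra = [rng.choice(sorted(child_ids))]
            members[extra[0]].diagnosis = Diagnosis.DIAGNOSED
        keep.add(sorted(extra)[0])
        for iid in diagnosed:
            if iid not in keep:
                members[iid].diagnosis = Diagnosis.NON_AUTISTIC
    else:
        pool = [i for i in sorted(members) if members[i].diagnosis is not Diagnosis.DIAGNOSED]
        while len(diagnosed) < cfg.min_diagnosed_per_family and pool:
            pick = pool.pop(int(rng.integers(len(pool))))
            members[pick].diagnosis = Diagnosis.DIAGNOSED
            diagnosed.append(pick)


def _draw_traits(
    members: dict[str, Individual], cfg: SimConfig, rng: np.random.Generator
) -> None:
    inst = cfg.instrument
    for ind in members.values():
        if ind.diagnosis is Diagnosis.DIAGNOSED:
            mu = cfg.norm_mean + cfg.k_dx * cfg.norm_sd
            sd = cfg.sd_dx * cfg.norm_sd
        else:
            mu = cfg.norm_mean + cfg.k_bg * cfg.norm_sd
            sd = cfg.sd_bg * cfg.norm_sd
        score = float(np.clip(rng.normal(mu, sd), cfg.score_min, cfg.score_max))
        new = ind.with_trait(round(score, 1), inst)
        ind.trait_score = new.trait_score
        ind.instrument = new.instrument
        ind.trait_group = new.trait_group


# ---------------------------------------------------------------------------
# Transmission


def _topological_members(family: Family) -> list[str]:
    order: list[str] = []
    placed: set[str] = set()
    pending = sorted(family.members)
    while pending:
        progressed = False
        for iid in list(pending):
            ind = family.members[iid]
            if all(p is None or p in placed for p in (ind.father_id, ind.mother_id)):
                order.append(iid)
                placed.add(iid)
                pending.remove(iid)
                progressed = True
        if not progressed:  # pragma: no cover - Family already rejects cycles
            raise SimulationError("pedigree not topologically orderable")
    return order


def _transmit(
    family: Family, founder_carrier: str, rng: np.random.Generator
) -> dict[str, int]:
    """Allele counts after honest Mendelian transmission from one het founder."""
    counts: dict[str, int] = {}
    for iid in _topological_members(family):
        ind = family.members[iid]
        if ind.is_founder:
            counts[iid] = 1 if iid == founder_carrier else 0
        else:
            inherited = 0
            for pid in (ind.father_id, ind.mother_id):
                pc = counts[pid]
                if pc == 2:
                    inherited += 1
                elif pc == 1:
                    inherited += int(rng.random() < 0.5)
            counts[iid] = inherited
    return counts


# ---------------------------------------------------------------------------
# Read evidence


def _draw_call(
    count: int, cfg: SimConfig, rng: np.random.Generator
) -> tuple[int, int]:
    depth = max(1, int(rng.poisson(cfg.depth_lambda)))
    if count == 1:
        frac = 0.5
    elif count == 2:
        frac = 1.0 - cfg.base_error_alt_fraction
    else:
        frac = cfg.base_error_alt_fraction
    return depth, int(rng.binomial(depth, frac))


def _draw_supported_het(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[int, int]:
    """Het read evidence guaranteed to pass the inherited support gate."""
    for _ in range(1000):
        depth, alt = _draw_call(1, cfg, rng)
        if depth >= 10 and alt / depth >= 0.34:
            return depth, alt
    raise SimulationError("could not draw supported het evidence")


def _draw_denovo_child(cfg: SimConfig, rng: np.random.Generator) -> tuple[int, int]:
    for _ in range(1000):
        depth, alt = _draw_call(1, cfg, rng)
        if depth > 20 and alt >= 8 and alt / depth > 0.40:
            return depth, alt
    raise SimulationError("could not draw de novo child evidence")


def _draw_clean_parent(cfg: SimConfig, rng: np.random.Generator) -> tuple[int, int]:
    for _ in range(1000):
        depth, alt = _draw_call(0, cfg, rng)
        if depth > 20 and alt / depth < 0.05:
            return depth, alt
    raise SimulationError("could not draw clean parental evidence")


# ---------------------------------------------------------------------------
# Main generator


@dataclass
class _Site:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    func_class: str
    maf: float | None
    sift: str | None
    polyphen: str | None
    pli: float | None
    loeuf: float | None
    tier: int | None
    counts: dict[str, int]  # individual -> alt allele count
    reads: dict[str, tuple[int, int]]  # individual -> (depth, alt_reads)


_BASES = ("A", "C", "G", "T")


def _new_site(index: int, gene: str, rng: np.random.Generator) -> tuple[str, int, str, str]:
    chrom = str(1 + index % 22)
    pos = 1_000_000 * (index + 1) + int(rng.integers(1, 900_000))
    ref = _BASES[int(rng.integers(4))]
    alt = _BASES[(int(_BASES.index(ref)) + 1 + int(rng.integers(3))) % 4]
    return chrom, pos, ref, alt


def _damaging_annotation(rng: np.random.Generator) -> tuple[str, str | None, str | None]:
    cls = ["nonsynonymous_snv", "stopgain", "frameshift_insertion", "frameshift_deletion"][
        int(rng.integers(4))
    ]
    if cls == "nonsynonymous_snv":
        return cls, "D", "D" if rng.random() < 0.7 else "P"
    return cls, None, None


def simulate_cohort(cfg: SimConfig, out_dir: str | Path) -> SimResult:
    """Generate the full bundle under ``out_dir``; see the module docstring."""
    rng = np.random.default_rng(cfg.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- pedigrees and phenotypes
    families: dict[str, Family] = {}
    if cfg.family_plan is not None and len(cfg.family_plan) != cfg.n_families:
        raise SimulationError(
            f"family_plan has {len(cfg.family_plan)} entries for "
            f"{cfg.n_families} families"
        )
    # place the under-recruited families last so plants target full families first
    fids = [f"F{i + 1:02d}" for i in range(cfg.n_families)]
    small_fids = set(list(reversed(fids))[: cfg.n_small_families])
    for i, fid in enumerate(fids):
        if cfg.family_plan is not None:
            n_children, n_dx = cfg.family_plan[i]
        else:
            n_children = int(
                rng.integers(cfg.children_range[0], cfg.children_range[1] + 1)
            )
            n_dx = None
        members = _build_family(fid, n_children, cfg.generations, rng)
        _assign_phenotypes(members, fid, fid in small_fids, cfg, rng, n_dx)
        families[fid] = Family(family_id=fid, members=members)
    # suspected status, cohort-wide, among non-diagnosed members
    all_nondx = sorted(
        iid
        for fam in families.values()
        for iid, m in fam.members.items()
        if m.diagnosis is Diagnosis.NON_AUTISTIC
    )
    for iid in rng.choice(all_nondx, size=min(cfg.n_suspected, len(all_nondx)), replace=False):
        fam = next(f for f in families.values() if iid in f.members)
        fam.members[iid].diagnosis = Diagnosis.SUSPECTED
    for fam in families.values():
        _draw_traits(fam.members, cfg, rng)

    # --- variants
    sites: list[_Site] = []
    truth: list[PlantedVariant] = []
    gene_counter = 0

    def next_gene() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"GENE{gene_counter:04d}"

    def generic_reads(counts: Mapping[str, int]) -> dict[str, tuple[int, int]]:
        return {
            iid: _draw_call(c, cfg, rng) for iid, c in sorted(counts.items())
        }

    def all_ids() -> Iterable[str]:
        for fam in families.values():
            yield from fam.members

    # diagnosis-segregating plants
    for fid in fids:
        fam = families[fid]
        for _ in range(cfg.n_planted_diagnosis_per_family):
            if len(fam.diagnosed) < 2:
                raise SimulationError(
                    f"family {fid}: cannot plant a diagnosis-segregating variant "
                    f"with {len(fam.diagnosed)} diagnosed members"
                )
            founders = [
                i
                for i in sorted(fam.members)
                if fam.members[i].is_founder
                and fam.members[i].diagnosis is Diagnosis.DIAGNOSED
            ]
            if not founders:
                raise SimulationError(f"family {fid}: no diagnosed founder to carry a plant")
            founder = founders[0]
            for attempt in range(cfg.max_plant_retries):
                counts = _transmit(fam, founder, rng)
                carriers = {i for i, c in counts.items() if c > 0}
                if (
                    len(carriers & fam.diagnosed) >= 2
                    and not carriers & fam.non_autistic
                ):
                    break
            else:
                raise SimulationError(
                    f"family {fid}: diagnosis plant unsatisfied after "
                    f"{cfg.max_plant_retries} transmissions"
                )
            gene = next_gene()
            chrom, pos, ref, alt = _new_site(len(sites), gene, rng)
            cls, sift, poly = _damaging_annotation(rng)
            reads = generic_reads({i: counts.get(i, 0) for i in all_ids()})
            for iid in sorted(carriers):
                reads[iid] = _draw_supported_het(cfg, rng)
            sites.append(
                _Site(
                    chrom, pos, ref, alt, gene, cls,
                    maf=None if rng.random() < 0.5 else round(float(rng.uniform(1e-4, 9e-3)), 6),
                    sift=sift, polyphen=poly,
                    pli=round(float(rng.uniform(0.9, 1.0)), 3),
                    loeuf=round(float(rng.uniform(0.05, 0.3)), 3),
                    tier=1,
                    counts={i: counts.get(i, 0) for i in all_ids()},
                    reads=reads,
                )
            )
            truth.append(
                PlantedVariant(
                    chrom, pos, ref, alt, gene, fid, "diagnosis", None,
                    tuple(sorted(carriers)),
                )
            )

    # trait-segregating plants
    for fid in fids:
        fam = families[fid]
        for _ in range(cfg.n_planted_trait_per_family):
            founders = [
                i
                for i in sorted(fam.members)
                if fam.members[i].is_founder
                and fam.members[i].trait_group is not None
                and fam.members[i].trait_group > TraitGroup.AVERAGE
            ]
            if not founders:
                continue  # no elevated founder: trait plant unsatisfiable here
            founder = founders[0]
            for attempt in range(cfg.max_plant_retries):
                counts = _transmit(fam, founder, rng)
                carriers = {i for i, c in counts.items() if c > 0}
                groups = [fam.members[i].trait_group for i in carriers]
                if len(carriers) >= 2 and all(
                    g is not None and g > TraitGroup.AVERAGE for g in groups
                ):
                    level = min(groups)
                    break
            else:
                continue
            gene = next_gene()
            chrom, pos, ref, alt = _new_site(len(sites), gene, rng)
            cls, sift, poly = _damaging_annotation(rng)
            reads = generic_reads({i: counts.get(i, 0) for i in all_ids()})
            for iid in sorted(carriers):
                reads[iid] = _draw_supported_het(cfg, rng)
            sites.append(
                _Site(
                    chrom, pos, ref, alt, gene, cls,
                    maf=None if rng.random() < 0.5 else round(float(rng.uniform(1e-4, 9e-3)), 6),
                    sift=sift, polyphen=poly,
                    pli=round(float(rng.uniform(0.9, 1.0)), 3),
                    loeuf=round(float(rng.uniform(0.05, 0.3)), 3),
                    tier=1 if rng.random() < 0.5 else 2,
                    counts={i: counts.get(i, 0) for i in all_ids()},
                    reads=reads,
                )
            )
            truth.append(
                PlantedVariant(
                    chrom, pos, ref, alt, gene, fid, "trait", level.name,
                    tuple(sorted(carriers)),
                )
            )

    # de novo plants in diagnosed trio children (the cohort design detects
    # de novo hits in autistic members), falling back to any child
    trio_children: list[tuple[str, str, str, str]] = []  # (fid, child, father, mother)
    for fid in fids:
        fam = families[fid]
        for iid in sorted(fam.members):
            ind = fam.members[iid]
            if ind.father_id is not None and ind.mother_id is not None:
                trio_children.append((fid, iid, ind.father_id, ind.mother_id))
    diagnosed_children = [
        t for t in trio_children
        if families[t[0]].members[t[1]].diagnosis is Diagnosis.DIAGNOSED
    ]
    if len(diagnosed_children) >= cfg.n_planted_denovo:
        trio_children = diagnosed_children
    if cfg.n_planted_denovo > 0 and not trio_children:
        raise SimulationError("no trios available for de novo plants")
    picks = rng.choice(len(trio_children), size=min(cfg.n_planted_denovo, len(trio_children)), replace=False)
    for idx in sorted(int(i) for i in picks):
        fid, child, father, mother = trio_children[idx]
        counts = {i: 0 for i in all_ids()}
        counts[child] = 1
        gene = next_gene()
        chrom, pos, ref, alt = _new_site(len(sites), gene, rng)
        cls, sift, poly = _damaging_annotation(rng)
        reads = generic_reads(counts)
        reads[child] = _draw_denovo_child(cfg, rng)
        reads[father] = _draw_clean_parent(cfg, rng)
        reads[mother] = _draw_clean_parent(cfg, rng)
        sites.append(
            _Site(
                chrom, pos, ref, alt, gene, cls,
                maf=None if rng.random() < 0.5 else round(float(rng.uniform(1e-4, 9e-3)), 6),
                sift=sift, polyphen=poly,
                pli=round(float(rng.uniform(0.9, 1.0)), 3),
                loeuf=round(float(rng.uniform(0.05, 0.3)), 3),
                tier=1,
                counts=counts,
                reads=reads,
            )
        )
        truth.append(
            PlantedVariant(chrom, pos, ref, alt, gene, fid, "de_novo", None, (child,))
        )

    # noise variants: honest transmission from a random founder, annotations
    # passing the damaging/constraint gates only at the configured rate
    all_founders = sorted(
        iid
        for fam in families.values()
        for iid, m in fam.members.items()
        if m.is_founder
    )
    all_trios = [
        (fam.members[iid].father_id, fam.members[iid].mother_id, iid)
        for fam in families.values()
        for iid in sorted(fam.members)
        if fam.members[iid].father_id is not None
    ]
    expected_viol = 0.0
    viol_var = 0.0
    for _ in range(cfg.n_noise_variants):
        founder = str(rng.choice(all_founders))
        fam = next(f for f in families.values() if founder in f.members)
        counts = {i: 0 for i in all_ids()}
        counts.update(_transmit(fam, founder, rng))
        if cfg.genotype_error_rate > 0:
            for f_id, m_id, c_id in all_trios:
                p = _trio_violation_prob(
                    counts[f_id], counts[m_id], counts[c_id], cfg.genotype_error_rate
                )
                expected_viol += p
                viol_var += p * (1 - p)
            for iid in sorted(counts):
                if rng.random() < cfg.genotype_error_rate:
                    counts[iid] = int(
                        rng.choice([c for c in (0, 1, 2) if c != counts[iid]])
                    )
        gene = next_gene()
        chrom, pos, ref, alt = _new_site(len(sites), gene, rng)
        if rng.random() < cfg.noise_annotation_pass_rate:
            cls, sift, poly = _damaging_annotation(rng)
            maf = None
            pli, loeuf = 0.97, 0.1
        else:
            # guaranteed-failing annotation: class, frequency and constraint
            cls, sift, poly = "synonymous", None, None
            maf = round(float(rng.uniform(0.02, 0.2)), 4)
            pli, loeuf = round(float(rng.uniform(0.0, 0.5)), 3), round(float(rng.uniform(0.5, 1.5)), 3)
        carriers = tuple(sorted(i for i, c in counts.items() if c > 0))
        sites.append(
            _Site(
                chrom, pos, ref, alt, gene, cls,
                maf=maf, sift=sift, polyphen=poly,
                pli=pli, loeuf=loeuf, tier=None,
                counts=counts, reads=generic_reads(counts),
            )
        )
        truth.append(
            PlantedVariant(chrom, pos, ref, alt, gene, fam.family_id, "noise", None, carriers)
        )

    paths = _write_bundle(cfg, families, sites, truth, out_dir)
    return SimResult(
        config=cfg,
        families=families,
        truth=truth,
        paths=paths,
        expected_noise_violations=expected_viol,
        noise_violation_variance=viol_var,
    )


from functools import lru_cache


@lru_cache(maxsize=None)
def _trio_violation_prob(tf: int, tm: int, tc: int, eps: float) -> float:
    """P(observed trio is Mendelian-inconsistent) under the error model.

    Each member's true genotype is replaced, independently with probability
    ``eps``, by one of the other two genotype states chosen uniformly.
    """

    def dist(true: int) -> list[tuple[int, float]]:
        out = []
        for g in (0, 1, 2):
            out.append((g, 1 - eps if g == true else eps / 2))
        return out

    p_viol = 0.0
    for f_obs, pf in dist(tf):
        for m_obs, pm in dist(tm):
            for c_obs, pc in dist(tc):
                if c_obs not in _allowed_child_counts(f_obs, m_obs):
                    p_viol += pf * pm * pc
    return p_viol


# ---------------------------------------------------------------------------
# Bundle writing


def _chrom_rank(chrom: str) -> int:
    try:
        return int(chrom.removeprefix("chr"))
    except ValueError:
        return 99


def _write_bundle(
    cfg: SimConfig,
    families: dict[str, Family],
    sites: list[_Site],
    truth: list[PlantedVariant],
    out_dir: Path,
) -> dict[str, Path]:
    paths = {
        "ped": out_dir / "cohort.ped",
        "traits": out_dir / "traits.csv",
        "norms": out_dir / "norms.yaml",
        "vcf": out_dir / "cohort.vcf",
        "annotations": out_dir / "annotations.tsv",
        "constraint": out_dir / "constraint.tsv",
        "tier_sources": out_dir / "tier_sources.yaml",
        "truth": out_dir / "truth.json",
    }
    fam_order = sorted(families)
    samples = [iid for fid in fam_order for iid in sorted(families[fid].members)]

    with open(paths["ped"], "w") as ped, open(paths["traits"], "w") as traits:
        traits.write("individual_id,instrument,score\n")
        for fid in fam_order:
            for iid in sorted(families[fid].members):
                ind = families[fid].members[iid]
                sex = {"male": "1", "female": "2"}.get(ind.sex, "0")
                ped.write(
                    f"{fid} {iid} {ind.father_id or 0} {ind.mother_id or 0} "
                    f"{sex} 0 {ind.diagnosis.value}\n"
                )
                traits.write(f"{iid},{cfg.instrument_name},{ind.trait_score}\n")
    with open(paths["norms"], "w") as fh:
        yaml.safe_dump(
            {cfg.instrument_name: {"mean": cfg.norm_mean, "sd": cfg.norm_sd}}, fh
        )

    with open(paths["annotations"], "w") as fh:
        cols = [
            "chrom", "pos", "ref", "alt", "gene", "func_class", "maf_nfe",
            "sift", "polyphen_hdiv", "dbsnp", "aa_change",
        ]
        fh.write("\t".join(cols) + "\n")
        for s in sites:
            fh.write(
                "\t".join(
                    [
                        s.chrom, str(s.pos), s.ref, s.alt, s.gene, s.func_class,
                        "." if s.maf is None else repr(s.maf),
                        s.sift or ".", s.polyphen or ".", ".", ".",
                    ]
                )
                + "\n"
            )
    with open(paths["constraint"], "w") as fh:
        fh.write("gene\tpli\tloeuf\n")
        for s in sites:
            fh.write(
                f"{s.gene}\t{'.' if s.pli is None else s.pli}"
                f"\t{'.' if s.loeuf is None else s.loeuf}\n"
            )

    tier_lists: dict[int, list[str]] = {1: [], 2: [], 3: []}
    for s in sites:
        if s.tier is not None:
            tier_lists[s.tier].append(s.gene)
    tier_cfg: dict[str, dict[str, str]] = {}
    for tier, genes in tier_lists.items():
        fname = f"tier{tier}_simulated.txt"
        with open(out_dir / fname, "w") as fh:
            fh.write("\n".join(sorted(genes)) + ("\n" if genes else ""))
        tier_cfg[f"tier{tier}"] = {f"simulated-tier{tier}": fname}
    with open(paths["tier_sources"], "w") as fh:
        yaml.safe_dump(tier_cfg, fh)

    header = pysam.VariantHeader()
    for c in sorted({s.chrom for s in sites}, key=_chrom_rank):
        header.contigs.add(c, length=260_000_000)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths")
    for sid in samples:
        header.add_sample(sid)
    with pysam.VariantFile(str(paths["vcf"]), "w", header=header) as vcf:
        for s in sorted(sites, key=lambda s: (_chrom_rank(s.chrom), s.pos)):
            rec = vcf.new_record(contig=s.chrom, start=s.pos - 1, alleles=(s.ref, s.alt))
            for sid in samples:
                count = s.counts.get(sid, 0)
                depth, alt_reads = s.reads.get(sid, (0, 0))
                call = rec.samples[sid]
                call["GT"] = ((0, 0), (0, 1), (1, 1))[count]
                call["DP"] = depth
                call["AD"] = (depth - alt_reads, alt_reads)
            vcf.write(rec)

    with open(paths["truth"], "w") as fh:
        json.dump([asdict(t) for t in truth], fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


# ---------------------------------------------------------------------------
# Mendelian consistency check


def _allowed_child_counts(fc: int, mc: int) -> set[int]:
    opts = {0: {0}, 1: {0, 1}, 2: {1}}
    return {i + j for i in opts[fc] for j in opts[mc]}


def mendelian_check(
    vcf_path: str | Path,
    families: Mapping[str, Family],
    exclude_sites: set[tuple[str, int, str, str]] = frozenset(),
) -> int:
    """Count trio genotype configurations impossible under Mendelian transmission.

    Sites listed in ``exclude_sites`` (e.g. planted de novos from the truth
    table) are skipped.  Missing genotypes are ignored.
    """
    from .variant_io import read_vcf

    children = [
        (fam.members[iid].father_id, fam.members[iid].mother_id, iid)
        for fam in families.values()
        for iid in sorted(fam.members)
        if fam.members[iid].father_id is not None
        and fam.members[iid].mother_id is not None
    ]
    state_count = {HOM_REF: 0, HET: 1, HOM_ALT: 2}
    violations = 0
    for site, calls in read_vcf(vcf_path):
        if site.key in exclude_sites:
            continue
        for fid_, mid_, cid_ in children:
            trio_calls = [calls.get(fid_), calls.get(mid_), calls.get(cid_)]
            if any(c is None or c.gt == "missing" for c in trio_calls):
                continue
            fc, mc, cc = (state_count[c.gt] for c in trio_calls)
            if cc not in _allowed_child_counts(fc, mc):
                violations += 1
    return violations
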