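"""Worked-example replay of the published prioritised-variant table.

Two fixtures live here:

1. :func:`load_reported_variants` parses the packaged summary table of
   prioritised hits (gene, family, trait/diagnosis label, site, predictors,
   tier) into :class:`~famseg.segregation.PrioritisedVariant` records, from
   which the cross-family Venn and tier tabulations are recomputed.

2. :func:`build_replay_bundle` inverse-constructs a complete synthetic
   cohort (PED, trait table, VCF, annotation/constraint tables, tier
   sources) whose genotypes realise one minimal configuration per reported
   row, so running the full pipeline on the bundle reproduces every row's
   label.  Each referenced family gets a fixed nine-member roster — a
   non-autistic father, a diagnosed NAP mother, diagnosed children in each
   trait band (NAP/MAP/BAP/AVERAGE) and undiagnosed scored children
   (NAP/MAP/BAP) — rich enough to realise every label type:

   * ``L/Diagnosis`` — carried by the mother and the diagnosed child in
     band L;
   * ``L`` alone — carried by the mother and the *undiagnosed* child in
     band L (one diagnosed carrier only, so the diagnosis rule stays off);
   * ``Diagnosis`` alone — carried by the mother and the diagnosed
     AVERAGE-band child (the AVERAGE carrier vetoes any trait label);
   * de novo rows — planted heterozygous in the matching child with clean
     parental reads.

   Inherited carriers always include the transmitting mother, keeping
   genotypes Mendelian-consistent and parental alt fractions high enough
   that no inherited variant leaks through the de novo filter.

All genotypes, scores and read depths here are synthetic constructions;
only the table of hits itself is reported data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .cohort import Diagnosis, Family, Individual, TraitGroup, TraitInstrument
from .segregation import PrioritisedVariant
from .variant_io import AnnotatedVariant, VariantSite

#: Synthetic adult-AQ norms used by every replay individual.
REPLAY_NORMS = {"adult-AQ": {"mean": 20.0, "sd": 5.0}}
_SCORES = {
    TraitGroup.NAP: 38.0,
    TraitGroup.MAP: 31.0,
    TraitGroup.BAP: 27.0,
    TraitGroup.AVERAGE: 20.0,
}

#: roster member -> (diagnosis, trait band)
_ROSTER = {
    "F": (Diagnosis.NON_AUTISTIC, TraitGroup.AVERAGE),
    "M": (Diagnosis.DIAGNOSED, TraitGroup.NAP),
    "C_NAP": (Diagnosis.DIAGNOSED, TraitGroup.NAP),
    "C_MAP": (Diagnosis.DIAGNOSED, TraitGroup.MAP),
    "C_BAP": (Diagnosis.DIAGNOSED, TraitGroup.BAP),
    "C_AVG": (Diagnosis.DIAGNOSED, TraitGroup.AVERAGE),
    "U_NAP": (Diagnosis.UNKNOWN, TraitGroup.NAP),
    "U_MAP": (Diagnosis.UNKNOWN, TraitGroup.MAP),
    "U_BAP": (Diagnosis.UNKNOWN, TraitGroup.BAP),
}


@dataclass(frozen=True)
class ReportedVariant:
    """One parsed row of the packaged summary table."""

    prioritised: PrioritisedVariant
    tier_source: str


def _parse_level(token: str) -> TraitGroup | None:
    return None if token == "." else TraitGroup[token]


def load_reported_variants() -> list[ReportedVariant]:
    text = (
        resources.files("famseg")
        .joinpath("data/reported_variants.tsv")
        .read_text()
    )
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    out: list[ReportedVariant] = []
    for row in reader:
        maf = row["maf_nfe"]
        av = AnnotatedVariant(
            site=VariantSite(
                row["chrom"], int(row["pos"]), row["ref"], row["alt"]
            ),
            gene=row["gene"],
            func_class=(
                "frameshift_deletion"
                if row["alt"] == "-"
                else "nonsynonymous_snv"
            ),
            maf_nfe=None if maf == "." else float(maf),
            sift=None if row["sift"] == "." else row["sift"],
            polyphen_hdiv=None if row["polyphen_hdiv"] == "." else row["polyphen_hdiv"],
            dbsnp=None if row["dbsnp"] == "." else row["dbsnp"],
            aa_change=row["aa_change"],
        )
        out.append(
            ReportedVariant(
                prioritised=PrioritisedVariant(
                    variant=av,
                    family_id=row["family"],
                    diagnosis_hit=row["diagnosis"] == "1",
                    trait_level=_parse_level(row["trait_level"]),
                    origin=row["origin"],
                    tier=int(row["tier"]),
                ),
                tier_source=row["tier_source"],
            )
        )
    return out


def reported_prioritised() -> list[PrioritisedVariant]:
    return [rv.prioritised for rv in load_reported_variants()]


def reported_gene_tiers() -> dict[str, int]:
    return {rv.prioritised.variant.gene: rv.prioritised.tier for rv in load_reported_variants()}


# ---------------------------------------------------------------------------
# Inverse-constructed cohort bundle


def _member_id(fam: str, role: str) -> str:
    return f"FAM{fam}_{role}"


def replay_families() -> dict[str, Family]:
    fams = sorted(
        {rv.prioritised.family_id for rv in load_reported_variants()},
        key=lambda f: int(f),
    )
    instrument = TraitInstrument("adult-AQ", 20.0, 5.0)
    out: dict[str, Family] = {}
    for fam in fams:
        members: dict[str, Individual] = {}
        father = _member_id(fam, "F")
        mother = _member_id(fam, "M")
        for role, (dx, band) in _ROSTER.items():
            iid = _member_id(fam, role)
            ind = Individual(
                individual_id=iid,
                family_id=fam,
                father_id=None if role in ("F", "M") else father,
                mother_id=None if role in ("F", "M") else mother,
                sex="male" if role == "F" else "female" if role == "M" else "unknown",
                diagnosis=dx,
            ).with_trait(_SCORES[band], instrument)
            members[iid] = ind
        out[fam] = Family(family_id=fam, members=members)
    return out


def _carrier_roles(pv: PrioritisedVariant) -> list[str]:
    """The minimal roster carrier set realising one row's label."""
    if pv.origin == "de_novo":
        if pv.trait_level is None:
            return ["C_AVG"]
        return [f"C_{pv.trait_level.name}"]
    if pv.diagnosis_hit and pv.trait_level is None:
        return ["M", "C_AVG"]
    band = pv.trait_level.name
    child = f"C_{band}" if pv.diagnosis_hit else f"U_{band}"
    return ["M", child]


def _vcf_site(pv: PrioritisedVariant) -> tuple[str, int, str, str]:
    """VCF-style (anchored) representation of the row's site."""
    s = pv.variant.site
    if s.alt == "-":  # dash-style deletion -> anchored base one position left
        return (s.chrom, s.pos - 1, "A" + s.ref, "A")
    if s.ref == "-":
        return (s.chrom, s.pos, "A", "A" + s.alt)
    return (s.chrom, s.pos, s.ref, s.alt)


def build_replay_bundle(out_dir: str | Path) -> dict[str, Path]:
    """Write the inverse-constructed cohort files; returns named paths."""
    import pysam

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reported = load_reported_variants()
    families = replay_families()
    fam_order = sorted(families, key=lambda f: int(f))

    paths = {
        "ped": out_dir / "cohort.ped",
        "traits": out_dir / "traits.csv",
        "norms": out_dir / "norms.yaml",
        "vcf": out_dir / "cohort.vcf",
        "annotations": out_dir / "annotations.tsv",
        "constraint": out_dir / "constraint.tsv",
        "tier_sources": out_dir / "tier_sources.yaml",
    }

    # PED + traits
    with open(paths["ped"], "w") as ped, open(paths["traits"], "w") as traits:
        traits.write("individual_id,instrument,score\n")
        for fam in fam_order:
            for ind in families[fam].members.values():
                sex = {"male": "1", "female": "2"}.get(ind.sex, "0")
                ped.write(
                    f"{fam} {ind.individual_id} {ind.father_id or 0} "
                    f"{ind.mother_id or 0} {sex} 0 {ind.diagnosis.value}\n"
                )
                traits.write(
                    f"{ind.individual_id},adult-AQ,{ind.trait_score}\n"
                )
    with open(paths["norms"], "w") as fh:
        yaml.safe_dump(REPLAY_NORMS, fh)

    # annotation + constraint tables (annotation keeps the dash style verbatim)
    genes = sorted({rv.prioritised.variant.gene for rv in reported})
    with open(paths["annotations"], "w") as fh:
        cols = [
            "chrom", "pos", "ref", "alt", "gene", "func_class", "maf_nfe",
            "sift", "polyphen_hdiv", "dbsnp", "aa_change",
        ]
        fh.write("\t".join(cols) + "\n")
        seen = set()
        for rv in reported:
            v = rv.prioritised.variant
            s = v.site
            if s.key in seen:
                continue
            seen.add(s.key)
            fh.write(
                "\t".join(
                    [
                        s.chrom, str(s.pos), s.ref, s.alt, v.gene,
                        v.func_class,
                        "." if v.maf_nfe is None else repr(v.maf_nfe),
                        v.sift or ".", v.polyphen_hdiv or ".",
                        v.dbsnp or ".", v.aa_change or ".",
                    ]
                )
                + "\n"
            )
    with open(paths["constraint"], "w") as fh:
        fh.write("gene\tpli\tloeuf\n")
        for gene in genes:
            fh.write(f"{gene}\t0.98\t0.15\n")

    # tier sources: copy the packaged synthetic stand-in lists
    from .tiers import fixture_tier_sources

    sources = fixture_tier_sources()
    cfg: dict[str, dict[str, str]] = {}
    for tier_key, named in (
        ("tier1", sources.tier1),
        ("tier2", sources.tier2),
        ("tier3", sources.tier3),
    ):
        cfg[tier_key] = {}
        for name, symbols in named.items():
            fname = f"{tier_key}_{name.replace('/', '_')}.synthetic.txt"
            with open(out_dir / fname, "w") as fh:
                fh.write("\n".join(sorted(symbols)) + "\n")
            cfg[tier_key][name] = fname
    with open(paths["tier_sources"], "w") as fh:
        yaml.safe_dump(cfg, fh)

    # VCF: one record per distinct site, carriers per row unioned
    samples = [
        ind
        for fam in fam_order
        for ind in sorted(families[fam].members)
    ]
    site_carriers: dict[tuple[str, int, str, str], set[str]] = {}
    denovo_children: dict[tuple[str, int, str, str], set[str]] = {}
    for rv in reported:
        pv = rv.prioritised
        key = _vcf_site(pv)
        roles = _carrier_roles(pv)
        ids = {_member_id(pv.family_id, r) for r in roles}
        site_carriers.setdefault(key, set()).update(ids)
        if pv.origin == "de_novo":
            denovo_children.setdefault(key, set()).update(ids)

    header = pysam.VariantHeader()
    chroms = sorted({k[0] for k in site_carriers}, key=_chrom_rank)
    for chrom in chroms:
        header.contigs.add(chrom, length=250_000_000)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths")
    for sid in samples:
        header.add_sample(sid)

    with pysam.VariantFile(str(paths["vcf"]), "w", header=header) as vcf:
        for key in sorted(site_carriers, key=lambda k: (_chrom_rank(k[0]), k[1])):
            chrom, pos, ref, alt = key
            rec = vcf.new_record(
                contig=chrom, start=pos - 1, alleles=(ref, alt), id="."
            )
            carriers = site_carriers[key]
            dn = denovo_children.get(key, set())
            for sid in samples:
                s = rec.samples[sid]
                if sid in carriers:
                    # de novo children get a 0.45 alt fraction, inherited
                    # carriers a balanced het
                    alt_reads = 18 if sid in dn else 20
                    s["GT"] = (0, 1)
                    s["DP"] = 40
                    s["AD"] = (40 - alt_reads, alt_reads)
                else:
                    s["GT"] = (0, 0)
                    s["DP"] = 40
                    s["AD"] = (40, 0)
            vcf.write(rec)
    return paths


def _chrom_rank(chrom: str) -> int:
    c = chrom.removeprefix("chr")
    try:
        return int(c)
    except ValueError:
        return 100 + ord(c[0])


# ---------------------------------------------------------------------------
# Carrier-status replay for the enrichment test


def study_carrier_replay() -> tuple[list[Individual], list[PrioritisedVariant], dict[str, int]]:
    """Deterministic synthetic cohort reproducing the reported carrier counts.

    112 members: 74 diagnosed (50 Tier-1 carriers), 4 suspected (excluded
    from the table) and 34 without a diagnosis (11 carriers), all carrying
    or not carrying one synthetic Tier-1 prioritised variant.
    """
    individuals: list[Individual] = []
    carriers: set[str] = set()

    def add(n: int, dx: Diagnosis, n_carriers: int, prefix: str) -> None:
        for i in range(n):
            iid = f"{prefix}{i:03d}"
            individuals.append(
                Individual(individual_id=iid, family_id="R1", diagnosis=dx)
            )
            if i < n_carriers:
                carriers.add(iid)

    add(74, Diagnosis.DIAGNOSED, 50, "DX")
    add(30, Diagnosis.NON_AUTISTIC, 10, "NA")
    add(4, Diagnosis.UNKNOWN, 1, "UN")
    add(4, Diagnosis.SUSPECTED, 2, "SU")

    av = AnnotatedVariant(
        site=VariantSite("1", 1_000_000, "A", "G"),
        gene="GENE_T1",
        func_class="stopgain",
    )
    pv = PrioritisedVariant(
        variant=av,
        family_id="R1",
        diagnosis_hit=True,
        trait_level=None,
        carriers=frozenset(carriers),
    )
    return individuals, [pv], {"GENE_T1": 1}
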