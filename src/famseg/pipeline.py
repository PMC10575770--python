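"""End-to-end orchestration: load → filter → segregate → de novo → tiers → enrich.

`run_all` drives the whole analysis from one configuration mapping and
writes a report bundle:

* ``report.tsv`` — prioritised variants (inherited + de novo) in the
  shared report layout;
* ``gene_summary.tsv`` — one row per distinct gene with families,
  approach classification, best trait level and tier;
* ``venn.json`` — both / trait-only / diagnosis-only gene counts;
* ``enrichment.json`` — the Tier-1 carrier 2×2 table with χ², df and p
  (omitted with a note when a margin is empty);
* ``manifest.json`` — config echo plus the variant-count funnel at each
  filter stage.

All analysis stages are deterministic; randomness lives only in the
synthetic-data generator.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import variant_io
from .cohort import Family, enumerate_trios, load_cohort
from .denovo import DeNovoConfig, candidate_to_prioritised, scan_trios
from .exceptions import UndefinedTestError
from .filters import FilterConfig, is_constrained, is_rare_damaging
from .segregation import PrioritisedVariant, prioritise_family, summarise_genes
from .stats import carrier_contingency, chi_square_2x2, tier1_carrier_status
from .tiers import annotate_all, load_tier_sources
from .variant_io import match_annotation, read_annotation_table, read_constraint_table, read_vcf

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: Path
    ped: Path
    annotations: Path
    constraint: Path
    out_dir: Path
    traits: Path | None = None
    norms: Path | None = None
    tier_sources: Path | None = None
    mode: str = "both"
    filters: FilterConfig = FilterConfig()
    denovo: DeNovoConfig = DeNovoConfig()

    @classmethod
    def from_mapping(cls, cfg: Mapping[str, Any], base: Path | None = None) -> "PipelineConfig":
        def resolve(key: str, required: bool = True) -> Path | None:
            val = cfg.get(key)
            if val is None:
                if required:
                    raise KeyError(f"pipeline config missing required path {key!r}")
                return None
            p = Path(val)
            return (base / p) if base is not None and not p.is_absolute() else p

        return cls(
            vcf=resolve("vcf"),
            ped=resolve("ped"),
            annotations=resolve("annotations"),
            constraint=resolve("constraint"),
            out_dir=resolve("out_dir"),
            traits=resolve("traits", required=False),
            norms=resolve("norms", required=False),
            tier_sources=resolve("tier_sources", required=False),
            mode=cfg.get("mode", "both"),
            filters=FilterConfig(**cfg.get("filters", {})),
            denovo=DeNovoConfig(**cfg.get("denovo", {})),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls.from_mapping(cfg, base=path.parent)


def run_all(cfg: PipelineConfig) -> dict[str, Any]:
    """Run every stage; returns the manifest (also written to out_dir)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    families = load_cohort(cfg.ped, cfg.traits, cfg.norms)
    constraints = read_constraint_table(cfg.constraint)
    annotations = read_annotation_table(cfg.annotations)

    # join genotypes to annotation; unmatched sites dropped with a count
    joined = []
    n_sites = 0
    unmatched = 0
    for site, calls in read_vcf(cfg.vcf):
        n_sites += 1
        av = match_annotation(site, annotations)
        if av is None:
            unmatched += 1
            continue
        joined.append((av, calls))
    if unmatched:
        log.info("dropped %d genotype sites without annotation", unmatched)

    n_rare_damaging = sum(1 for av, _ in joined if is_rare_damaging(av, cfg.filters))
    n_constrained = sum(
        1
        for av, _ in joined
        if is_rare_damaging(av, cfg.filters)
        and is_constrained(constraints.get(av.gene), cfg.filters)
    )

    prioritised: list[PrioritisedVariant] = []
    for fid in sorted(families):
        prioritised.extend(
            prioritise_family(families[fid], joined, constraints, cfg.filters, cfg.mode)
        )
    n_inherited = len(prioritised)

    sample_ids = {iid for fam in families.values() for iid in fam.members}
    trios = [
        t for fid in sorted(families) for t in enumerate_trios(families[fid], sample_ids)
    ]
    candidates = scan_trios(trios, joined, constraints, cfg.denovo)
    denovo_pv = [
        pv for pv in (candidate_to_prioritised(c) for c in candidates) if pv is not None
    ]
    prioritised.extend(denovo_pv)

    genes = sorted({pv.variant.gene for pv in prioritised})
    if cfg.tier_sources is not None:
        sources = load_tier_sources(cfg.tier_sources)
        tier_map = {g: a.tier for g, a in annotate_all(genes, sources).items()}
    else:
        tier_map = {g: None for g in genes}
    prioritised = [
        PrioritisedVariant(
            variant=pv.variant,
            family_id=pv.family_id,
            diagnosis_hit=pv.diagnosis_hit,
            trait_level=pv.trait_level,
            origin=pv.origin,
            carriers=pv.carriers,
            tier=tier_map.get(pv.variant.gene),
        )
        for pv in prioritised
    ]

    summaries, venn = summarise_genes(prioritised, tier_map)
    variant_io.write_report([pv.to_report_row() for pv in prioritised], out / "report.tsv")
    with open(out / "gene_summary.tsv", "w") as fh:
        fh.write("gene\tfamilies\tapproaches\tbest_trait_level\ttier\n")
        for s in summaries:
            fh.write(
                f"{s.gene}\t{','.join(s.families)}\t{s.approaches}\t"
                f"{s.best_trait_level.name if s.best_trait_level else '.'}\t"
                f"{s.tier if s.tier is not None else '.'}\n"
            )
    with open(out / "venn.json", "w") as fh:
        json.dump(venn, fh, indent=1, sort_keys=True)
        fh.write("\n")

    individuals = [m for fam in families.values() for m in fam.members.values()]
    flags = tier1_carrier_status(individuals, prioritised, tier_map)
    enrichment: dict[str, Any]
    try:
        table = carrier_contingency(individuals, flags)
        res = chi_square_2x2(table)
        enrichment = {
            "a": table.a, "b": table.b, "c": table.c, "d": table.d,
            "n": table.n, "chi2": res.chi2, "df": res.df, "p": res.p,
            "odds_ratio": res.odds_ratio,
        }
    except UndefinedTestError as exc:
        enrichment = {"error": str(exc)}
    with open(out / "enrichment.json", "w") as fh:
        json.dump(enrichment, fh, indent=1, sort_keys=True)
        fh.write("\n")

    manifest = {
        "mode": cfg.mode,
        "filters": asdict(cfg.filters),
        "denovo": asdict(cfg.denovo),
        "counts": {
            "families": len(families),
            "individuals": len(individuals),
            "trios": len(trios),
            "vcf_sites": n_sites,
            "annotated_sites": len(joined),
            "rare_damaging": n_rare_damaging,
            "rare_damaging_constrained": n_constrained,
            "prioritised_inherited": n_inherited,
            "denovo_candidates": len(candidates),
            "prioritised_total": len(prioritised),
            "genes": len(genes),
        },
        "venn": venn,
        "enrichment": enrichment,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
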