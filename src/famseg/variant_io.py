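"""Readers and writers for the formats the pipeline touches.

Multi-sample VCF (via pysam), Annovar-style annotation tables, gnomAD-style
gene-constraint tables, plain gene lists, and the tab-separated
prioritisation report.  Coordinates are 1-based VCF convention throughout;
multi-allelic records are decomposed into biallelic sites and annotation is
joined by exact (chrom, pos, ref, alt) match, with the Annovar "C/-" indel
style accepted and normalised on the VCF side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import pysam

from .exceptions import InputError

log = logging.getLogger(__name__)

# genotype states
HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"

FUNC_CLASSES = (
    "nonsynonymous_snv",
    "stopgain",
    "stoploss",
    "frameshift_insertion",
    "frameshift_deletion",
    "splicing",
    "synonymous",
    "other",
)

#: Annovar / free-text tokens normalised onto the closed functional-class set.
_FUNC_TOKENS = {
    "nonsynonymous snv": "nonsynonymous_snv",
    "nonsynonymous_snv": "nonsynonymous_snv",
    "missense": "nonsynonymous_snv",
    "stopgain": "stopgain",
    "stop-gain": "stopgain",
    "stop_gain": "stopgain",
    "stoploss": "stoploss",
    "stop-loss": "stoploss",
    "stop_loss": "stoploss",
    "frameshift insertion": "frameshift_insertion",
    "frameshift_insertion": "frameshift_insertion",
    "frameshift deletion": "frameshift_deletion",
    "frameshift_deletion": "frameshift_deletion",
    "splicing": "splicing",
    "splice": "splicing",
    "synonymous snv": "synonymous",
    "synonymous_snv": "synonymous",
    "synonymous": "synonymous",
    "other": "other",
}


@dataclass(frozen=True, order=True)
class VariantSite:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise InputError(f"ref == alt at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class GenotypeCall:
    individual_id: str
    gt: str  # hom_ref / het / hom_alt / missing
    depth: int | None = None
    alt_reads: int | None = None

    def __post_init__(self) -> None:
        if (
            self.depth is not None
            and self.alt_reads is not None
            and not (0 <= self.alt_reads <= self.depth)
        ):
            raise InputError(
                f"{self.individual_id}: alt_reads {self.alt_reads} outside "
                f"[0, depth={self.depth}]"
            )

    @property
    def carries_alt(self) -> bool:
        return self.gt in (HET, HOM_ALT)


@dataclass(frozen=True)
class AnnotatedVariant:
    site: VariantSite
    gene: str
    func_class: str = "other"
    maf_nfe: float | None = None
    sift: str | None = None  # D / T
    polyphen_hdiv: str | None = None  # D / P / B
    dbsnp: str | None = None
    aa_change: str | None = None

    def __post_init__(self) -> None:
        if self.maf_nfe is not None and not (0.0 <= self.maf_nfe <= 1.0):
            raise InputError(f"maf_nfe {self.maf_nfe} outside [0, 1]")


@dataclass(frozen=True)
class GeneConstraint:
    gene: str
    pli: float | None = None
    loeuf: float | None = None

    def __post_init__(self) -> None:
        if self.pli is not None and not (0.0 <= self.pli <= 1.0):
            raise InputError(f"{self.gene}: pLI {self.pli} outside [0, 1]")
        if self.loeuf is not None and self.loeuf < 0:
            raise InputError(f"{self.gene}: negative LOEUF {self.loeuf}")


def normalise_func_class(token: str) -> str:
    tok = token.strip().lower().replace(";", " ").strip()
    cls = _FUNC_TOKENS.get(tok)
    if cls is None:
        log.warning("unknown functional class token %r -> 'other'", token)
        return "other"
    return cls


# ---------------------------------------------------------------------------
# VCF


def _decompose_gt(
    alleles: tuple[int | None, ...] | None, alt_index: int
) -> tuple[str, int]:
    """Genotype state for one decomposed alt allele; other alts act as ref."""
    if alleles is None or any(a is None for a in alleles):
        return MISSING, 0
    count = sum(1 for a in alleles if a == alt_index)
    return (HOM_REF, HET, HOM_ALT)[count], count


def read_vcf(
    path: str | Path, sample_ids: Sequence[str] | None = None
) -> Iterator[tuple[VariantSite, dict[str, GenotypeCall]]]:
    """Stream biallelic sites with per-sample genotype calls.

    Multi-allelic records are decomposed: one site per alternate allele,
    genotypes re-expressed against that allele (other alternates count as
    reference), AD split per allele.  Missing GT/DP/AD become ``None`` /
    ``missing`` markers.
    """
    with pysam.VariantFile(str(path)) as vcf:
        available = list(vcf.header.samples)
        if sample_ids is None:
            sample_ids = available
        else:
            absent = set(sample_ids) - set(available)
            if absent:
                raise InputError(f"samples not in VCF: {sorted(absent)}")
        for rec in vcf:
            alts = rec.alts or ()
            for k, alt in enumerate(alts, start=1):
                if alt is None or alt in ("*", "<NON_REF>"):
                    continue
                site = VariantSite(str(rec.chrom), int(rec.pos), str(rec.ref), str(alt))
                calls: dict[str, GenotypeCall] = {}
                for sid in sample_ids:
                    s = rec.samples[sid]
                    gt_state, _ = _decompose_gt(s.get("GT"), k)
                    ad = s.get("AD")
                    alt_reads = None
                    depth = s.get("DP")
                    if ad is not None and len(ad) > k and ad[k] is not None:
                        alt_reads = int(ad[k])
                        if depth is None:
                            depth = sum(int(x) for x in ad if x is not None)
                    calls[sid] = GenotypeCall(
                        individual_id=sid,
                        gt=gt_state,
                        depth=None if depth is None else int(depth),
                        alt_reads=alt_reads,
                    )
                yield site, calls


def annovar_style_key(site: VariantSite) -> tuple[str, int, str, str] | None:
    """The Annovar "-"-style key equivalent to an anchored VCF indel site.

    A deletion ``pos REF=AC ALT=A`` is Annovar ``pos+1 C/-``; an insertion
    ``pos REF=A ALT=AC`` is Annovar ``pos C`` inserted, i.e. ``-/C``.
    Returns None for non-indels or non-anchored representations.
    """
    ref, alt = site.ref, site.alt
    if len(ref) > 1 and alt == ref[0]:
        return (site.chrom, site.pos + 1, ref[1:], "-")
    if len(alt) > 1 and ref == alt[0]:
        return (site.chrom, site.pos, "-", alt[1:])
    return None


# ---------------------------------------------------------------------------
# Tables

DEFAULT_ANNOTATION_COLUMNS = {
    "chrom": "chrom",
    "pos": "pos",
    "ref": "ref",
    "alt": "alt",
    "gene": "gene",
    "func_class": "func_class",
    "maf_nfe": "maf_nfe",
    "sift": "sift",
    "polyphen_hdiv": "polyphen_hdiv",
    "dbsnp": "dbsnp",
    "aa_change": "aa_change",
}


def _clean(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return None if s in (".", "", "NA", "nan") else s


def read_annotation_table(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> dict[tuple[str, int, str, str], AnnotatedVariant]:
    """Load an Annovar-style TSV into a site-keyed annotation map."""
    cols = dict(DEFAULT_ANNOTATION_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.empty:
        return {}
    missing = {cols[c] for c in ("chrom", "pos", "ref", "alt", "gene")} - set(
        df.columns
    )
    if missing:
        raise InputError(f"{path}: annotation table missing columns {sorted(missing)}")
    out: dict[tuple[str, int, str, str], AnnotatedVariant] = {}
    for _, row in df.iterrows():
        chrom = str(row[cols["chrom"]])
        pos = int(row[cols["pos"]])
        ref = str(row[cols["ref"]])
        alt = str(row[cols["alt"]])
        maf = _clean(row.get(cols["maf_nfe"]))
        av = AnnotatedVariant(
            # "-" alleles (Annovar indel style) are kept verbatim in the key
            site=VariantSite(chrom, pos, ref, alt),
            gene=str(row[cols["gene"]]).upper(),
            func_class=normalise_func_class(str(row.get(cols["func_class"], "other"))),
            maf_nfe=None if maf is None else float(maf),
            sift=_clean(row.get(cols["sift"])),
            polyphen_hdiv=_clean(row.get(cols["polyphen_hdiv"])),
            dbsnp=_clean(row.get(cols["dbsnp"])),
            aa_change=_clean(row.get(cols["aa_change"])),
        )
        out[(chrom, pos, ref, alt)] = av
    return out


def match_annotation(
    site: VariantSite,
    annotations: Mapping[tuple[str, int, str, str], AnnotatedVariant],
) -> AnnotatedVariant | None:
    """Join a decomposed VCF site to its annotation row, if any.

    Tries the exact (chrom, pos, ref, alt) key first, then the equivalent
    Annovar dash-style indel key.
    """
    av = annotations.get(site.key)
    if av is None:
        alt_key = annovar_style_key(site)
        if alt_key is not None:
            av = annotations.get(alt_key)
    if av is None:
        return None
    # re-key onto the VCF site so downstream joins stay exact
    return AnnotatedVariant(
        site=site,
        gene=av.gene,
        func_class=av.func_class,
        maf_nfe=av.maf_nfe,
        sift=av.sift,
        polyphen_hdiv=av.polyphen_hdiv,
        dbsnp=av.dbsnp,
        aa_change=av.aa_change,
    )


def read_gene_list(path: str | Path) -> set[str]:
    """One symbol per line; uppercased and deduplicated."""
    symbols: set[str] = set()
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                symbols.add(sym.upper())
    return symbols


def read_constraint_table(path: str | Path) -> dict[str, GeneConstraint]:
    """TSV with columns gene, pli, loeuf; '.' means absent."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"gene", "pli", "loeuf"} - set(df.columns)
    if required:
        raise InputError(f"{path}: constraint table missing columns {sorted(required)}")
    out: dict[str, GeneConstraint] = {}
    for _, row in df.iterrows():
        gene = str(row["gene"]).upper()
        pli = _clean(row["pli"])
        loeuf = _clean(row["loeuf"])
        try:
            out[gene] = GeneConstraint(
                gene=gene,
                pli=None if pli is None else float(pli),
                loeuf=None if loeuf is None else float(loeuf),
            )
        except ValueError as exc:
            raise InputError(f"{path}: non-numeric constraint for {gene}: {exc}")
    return out


# ---------------------------------------------------------------------------
# Report

REPORT_COLUMNS = [
    "gene",
    "origin",
    "family",
    "label",
    "chrom_pos",
    "ref_alt",
    "aa_change",
    "dbsnp",
    "maf_nfe",
    "sift",
    "polyphen_hdiv",
    "tier",
    "carriers",
]


@dataclass(frozen=True)
class ReportRow:
    """One line of the prioritisation report (Table-style layout)."""

    gene: str
    origin: str  # inherited / de_novo
    family: str
    label: str  # e.g. "NAP/Diagnosis", "MAP", "Diagnosis"
    chrom_pos: str
    ref_alt: str
    aa_change: str | None = None
    dbsnp: str | None = None
    maf_nfe: float | None = None
    sift: str | None = None
    polyphen_hdiv: str | None = None
    tier: int | None = None
    carriers: tuple[str, ...] = ()


def _row_sort_key(r: ReportRow):
    return (r.tier if r.tier is not None else 99, r.gene, r.family, r.chrom_pos)


def write_report(rows: Iterable[ReportRow], path: str | Path) -> None:
    """Write the prioritisation report TSV, deterministically ordered."""
    ordered = sorted(rows, key=_row_sort_key)
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for r in ordered:
            fields = [
                r.gene,
                r.origin,
                r.family,
                r.label,
                r.chrom_pos,
                r.ref_alt,
                r.aa_change or ".",
                r.dbsnp or ".",
                "." if r.maf_nfe is None else repr(r.maf_nfe),
                r.sift or ".",
                r.polyphen_hdiv or ".",
                "." if r.tier is None else str(r.tier),
                ",".join(r.carriers) if r.carriers else ".",
            ]
            fh.write("\t".join(fields) + "\n")


def read_report(path: str | Path) -> list[ReportRow]:
    """Parse a report written by :func:`write_report` (round-trip inverse)."""
    rows: list[ReportRow] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != REPORT_COLUMNS:
            raise InputError(f"{path}: unexpected report header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            rows.append(
                ReportRow(
                    gene=f[0],
                    origin=f[1],
                    family=f[2],
                    label=f[3],
                    chrom_pos=f[4],
                    ref_alt=f[5],
                    aa_change=None if f[6] == "." else f[6],
                    dbsnp=None if f[7] == "." else f[7],
                    maf_nfe=None if f[8] == "." else float(f[8]),
                    sift=None if f[9] == "." else f[9],
                    polyphen_hdiv=None if f[10] == "." else f[10],
                    tier=None if f[11] == "." else int(f[11]),
                    carriers=() if f[12] == "." else tuple(f[12].split(",")),
                )
            )
    return rows
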