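"""Variant-level and gene-level eligibility filters.

These gates run before any within-family segregation logic:

* read support — every retained call needs ≥10 reads, and heterozygous
  calls need ≥33% of reads on the alternate allele;
* rarity + damage — gnomAD NFE frequency below 1% (absence from gnomAD is
  treated as rare), and a qualifying functional class: protein-truncating
  classes always qualify, missense only when SIFT calls it deleterious and
  PolyPhen-2 HDIV at least possibly damaging;
* gene constraint — pLI ≥ 0.9 or LOEUF < 0.37 (first decile), union by
  default and configurable to intersection or single-metric modes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import ConfigError
from .variant_io import AnnotatedVariant, GeneConstraint, GenotypeCall, HET

CONSTRAINT_MODES = ("union", "intersection", "pli_only", "loeuf_only")

#: Functional classes that qualify as damaging irrespective of predictors.
TRUNCATING_CLASSES = frozenset(
    {"stopgain", "stoploss", "frameshift_insertion", "frameshift_deletion"}
)


@dataclass(frozen=True)
class FilterConfig:
    maf_threshold: float = 0.01
    maf_inclusive: bool = False  # inherited filter uses strict "<1%"
    min_depth: int = 10
    min_het_alt_fraction: float = 0.33
    pli_threshold: float = 0.9
    loeuf_threshold: float = 0.37
    constraint_mode: str = "union"
    missing_maf_is_rare: bool = True
    splicing_qualifies: bool = False  # True in the de novo branch

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_threshold <= 1.0):
            raise ConfigError("maf_threshold must be in [0, 1]")
        if self.min_depth < 0:
            raise ConfigError("min_depth must be >= 0")
        if not (0.0 <= self.min_het_alt_fraction <= 1.0):
            raise ConfigError("min_het_alt_fraction must be in [0, 1]")
        if not (0.0 <= self.pli_threshold <= 1.0):
            raise ConfigError("pli_threshold must be in [0, 1]")
        if self.loeuf_threshold < 0:
            raise ConfigError("loeuf_threshold must be >= 0")
        if self.constraint_mode not in CONSTRAINT_MODES:
            raise ConfigError(f"constraint_mode must be one of {CONSTRAINT_MODES}")


def passes_read_support(call: GenotypeCall, cfg: FilterConfig) -> bool:
    """Read-depth and het allele-fraction gate; missing evidence fails closed."""
    if call.depth is None or call.depth < cfg.min_depth:
        return False
    if call.gt == HET:
        if call.alt_reads is None:
            return False
        return call.alt_reads / call.depth >= cfg.min_het_alt_fraction
    return True


def _is_rare(maf: float | None, cfg: FilterConfig) -> bool:
    if maf is None:
        return cfg.missing_maf_is_rare
    if cfg.maf_inclusive:
        return maf <= cfg.maf_threshold
    return maf < cfg.maf_threshold


def is_rare_damaging(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """Population-frequency and functional-damage gate."""
    if not _is_rare(v.maf_nfe, cfg):
        return False
    if v.func_class in TRUNCATING_CLASSES:
        return True
    if v.func_class == "splicing":
        return cfg.splicing_qualifies
    if v.func_class == "nonsynonymous_snv":
        return v.sift == "D" and v.polyphen_hdiv in ("D", "P")
    return False


def is_constrained(gc: GeneConstraint | None, cfg: FilterConfig) -> bool:
    """Gene eligibility under the configured pLI/LOEUF combination.

    A gene absent from the constraint table (``gc is None``) never passes.
    """
    if gc is None:
        return False
    pli_ok = gc.pli is not None and gc.pli >= cfg.pli_threshold
    loeuf_ok = gc.loeuf is not None and gc.loeuf < cfg.loeuf_threshold
    if cfg.constraint_mode == "union":
        return pli_ok or loeuf_ok
    if cfg.constraint_mode == "intersection":
        return pli_ok and loeuf_ok
    if cfg.constraint_mode == "pli_only":
        return pli_ok
    return loeuf_ok
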