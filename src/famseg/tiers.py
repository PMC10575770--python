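"""Evidence-tier classification of candidate genes.

Genes are placed into three tiers from user-supplied gene lists:

* Tier 1 — robust association with autism or severe neurodevelopmental
  conditions (e.g. SFARI categories S/1-3, SPARK, large exome studies,
  DDG2P monoallelic, DBDGD);
* Tier 2 — suggestive evidence for autism, intellectual disability,
  epilepsy or ADHD (e.g. AutDB, Gene4Denovo, autismKB, EpilepsyGene,
  IDGenetics, sysID, ADHDgene);
* Tier 3 — brain-expressed or synaptic genes (e.g. brain atlases,
  SynaptomeDB).

Precedence is 1 > 2 > 3: a gene's tier is the highest-precedence tier with
at least one supporting source.  Symbols are matched verbatim after
uppercasing; alias resolution is a documented extension point.

Real database snapshots are not bundled (licensing/versioning); the package
ships small synthetic stand-in lists sufficient for its worked examples and
documents the one-symbol-per-line file format for full lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .variant_io import read_gene_list


@dataclass(frozen=True)
class TierSources:
    """Named gene sets per tier; precedence 1 > 2 > 3."""

    tier1: Mapping[str, frozenset[str]] = field(default_factory=dict)
    tier2: Mapping[str, frozenset[str]] = field(default_factory=dict)
    tier3: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def by_tier(self) -> list[tuple[int, Mapping[str, frozenset[str]]]]:
        return [(1, self.tier1), (2, self.tier2), (3, self.tier3)]


@dataclass(frozen=True)
class TierAssignment:
    gene: str
    tier: int | None  # 1 / 2 / 3 / None
    supporting_sources: frozenset[str]


def assign_tier(gene: str, sources: TierSources) -> TierAssignment:
    sym = gene.upper()
    for tier, named_sets in sources.by_tier():
        support = frozenset(
            name for name, genes in named_sets.items() if sym in genes
        )
        if support:
            return TierAssignment(gene=sym, tier=tier, supporting_sources=support)
    return TierAssignment(gene=sym, tier=None, supporting_sources=frozenset())


def annotate_all(
    genes: Iterable[str], sources: TierSources
) -> dict[str, TierAssignment]:
    """Pure mapping gene -> assignment; unlisted genes get tier None."""
    return {g.upper(): assign_tier(g, sources) for g in genes}


def load_tier_sources(config_path: str | Path) -> TierSources:
    """Load a YAML config ``tier1/tier2/tier3 -> source-name -> list-file``.

    Relative list paths are resolved against the config file's directory.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    base = config_path.parent

    def load_tier(key: str) -> dict[str, frozenset[str]]:
        out = {}
        for name, path in (cfg.get(key) or {}).items():
            p = Path(path)
            if not p.is_absolute():
                p = base / p
            out[name] = frozenset(read_gene_list(p))
        return out

    return TierSources(
        tier1=load_tier("tier1"), tier2=load_tier("tier2"), tier3=load_tier("tier3")
    )


def fixture_tier_sources() -> TierSources:
    """The bundled synthetic stand-in source lists (worked-example scale)."""
    root = resources.files("famseg").joinpath("data/tier_fixture")

    def read(name: str) -> frozenset[str]:
        text = root.joinpath(name).read_text()
        return frozenset(
            line.strip().upper()
            for line in text.splitlines()
            if line.strip() and not line.startswith("#")
        )

    return TierSources(
        tier1={
            "SFARI": read("tier1_sfari.synthetic.txt"),
            "DDG2P-monoallelic": read("tier1_ddg2p_monoallelic.synthetic.txt"),
            "DBDGD": read("tier1_dbdgd.synthetic.txt"),
        },
        tier2={"AutDB": read("tier2_autdb.synthetic.txt")},
        tier3={"SynaptomeDB": read("tier3_synaptomedb.synthetic.txt")},
    )
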