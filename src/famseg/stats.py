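"""Carrier tabulation and the 2×2 carrier-enrichment chi-square test.

The enrichment question: are diagnosed family members more often carriers
of a prioritised rare variant in a Tier-1 gene than members without a
diagnosis?  Carrier status is cross-tabulated against diagnosis in a 2×2
table (suspected-diagnosis members are excluded from both rows) and tested
with the uncorrected Pearson chi-square on 1 df,

    χ² = N(ad − bc)² / ((a+b)(c+d)(a+c)(b+d)).

No continuity correction is applied by default; a Yates-corrected variant
is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats as _scipy_stats

from .cohort import Diagnosis, Individual, TraitGroup
from .exceptions import UndefinedTestError
from .segregation import GeneSummary, PrioritisedVariant


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Row 1: diagnosed carriers / non-carriers; row 2: non-diagnosed."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class ContingencyResult:
    chi2: float
    df: int
    p: float
    odds_ratio: float | None


def chi_square_2x2(
    t: ContingencyTable2x2, continuity_correction: bool = False
) -> ContingencyResult:
    """Pearson chi-square on a 2×2 table, 1 df, upper-tail p-value.

    With ``continuity_correction`` the Yates-adjusted statistic
    N(|ad−bc| − N/2)² / ∏margins (floored at zero) is used instead.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    margins = (a + b, c + d, a + c, b + d)
    if n == 0 or 0 in margins:
        raise UndefinedTestError(f"chi-square undefined for margins {margins}")
    cross = a * d - b * c
    if continuity_correction:
        adj = max(0.0, abs(cross) - n / 2)
        chi2 = n * adj * adj
    else:
        chi2 = n * cross * cross
    chi2 /= margins[0] * margins[1] * margins[2] * margins[3]
    p = float(_scipy_stats.chi2.sf(chi2, df=1))
    odds_ratio = (a * d) / (b * c) if b * c != 0 and a * d != 0 else None
    return ContingencyResult(chi2=float(chi2), df=1, p=p, odds_ratio=odds_ratio)


def tier1_carrier_status(
    individuals: Iterable[Individual],
    prioritised: Iterable[PrioritisedVariant],
    tiers: Mapping[str, int | None],
) -> dict[str, bool]:
    """Flag each individual carrying ≥1 prioritised Tier-1 variant.

    Carrier sets on the prioritised variants already hold only
    read-support-passing alt carriers.
    """
    tier1_carriers: set[str] = set()
    for pv in prioritised:
        if tiers.get(pv.variant.gene) == 1:
            tier1_carriers.update(pv.carriers)
    return {
        ind.individual_id: ind.individual_id in tier1_carriers for ind in individuals
    }


def carrier_contingency(
    individuals: Sequence[Individual], carrier_flags: Mapping[str, bool]
) -> ContingencyTable2x2:
    """Cross-tabulate carrier status against diagnosis.

    Suspected-diagnosis members are excluded entirely; unknown-status
    members are pooled with the non-diagnosed, matching a "without an
    autism diagnosis and not suspecting one" comparison group.
    """
    a = b = c = d = 0
    for ind in individuals:
        if ind.diagnosis is Diagnosis.SUSPECTED:
            continue
        carrier = carrier_flags.get(ind.individual_id, False)
        if ind.diagnosis is Diagnosis.DIAGNOSED:
            a, b = (a + 1, b) if carrier else (a, b + 1)
        else:
            c, d = (c + 1, d) if carrier else (c, d + 1)
    return ContingencyTable2x2(a=a, b=b, c=c, d=d)


def tier1_trait_distribution(
    summaries: Iterable[GeneSummary],
) -> dict[TraitGroup, int]:
    """Distinct Tier-1 genes per trait subgroup label.

    A gene counts in every subgroup for which it has at least one
    prioritised variant labelled with that subgroup; a gene labelled MAP in
    one family and NAP in another counts in both.
    """
    counts = {TraitGroup.BAP: 0, TraitGroup.MAP: 0, TraitGroup.NAP: 0}
    for summary in summaries:
        if summary.tier != 1:
            continue
        for level in summary.trait_levels:
            if level in counts:
                counts[level] += 1
    return counts
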