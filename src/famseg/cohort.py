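"""Families, individuals, diagnosis status and autistic-trait subgroups.

The cohort model mirrors a highly multiplex family study design: families
ascertained for carrying three or more diagnosed autistic members, every
participant scored on an age-appropriate autistic-trait instrument (adult,
adolescent or child AQ, or Q-CHAT for toddlers).  Trait scores are mapped
onto four ordered subgroups relative to the instrument's normative mean:

* ``AVERAGE`` — below one normative SD above the mean,
* ``BAP``     — broad autistic phenotype, [mean+1·SD, mean+2·SD),
* ``MAP``     — medium autistic phenotype, [mean+2·SD, mean+3·SD),
* ``NAP``     — narrow autistic phenotype, ≥ mean+3·SD.

Bands are closed at the lower edge and open at the top so the four groups
partition the score line.  Normative means and SDs are configuration, not
constants: they are instrument- and norm-sample-specific and must be
supplied by the user.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum, IntEnum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ConfigError, InputError, PedigreeError

log = logging.getLogger(__name__)

#: The closed set of supported trait instruments.
INSTRUMENT_NAMES = ("adult-AQ", "adolescent-AQ", "child-AQ", "Q-CHAT")

FOUNDER = "0"


class TraitGroup(IntEnum):
    """Ordered autistic-trait subgroup; AVERAGE < BAP < MAP < NAP."""

    AVERAGE = 0
    BAP = 1
    MAP = 2
    NAP = 3


class Diagnosis(str, Enum):
    DIAGNOSED = "diagnosed"
    SUSPECTED = "suspected"
    NON_AUTISTIC = "non_autistic"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class TraitInstrument:
    """A trait questionnaire with its normative mean and SD."""

    name: str
    norm_mean: float
    norm_sd: float

    def __post_init__(self) -> None:
        if self.name not in INSTRUMENT_NAMES:
            raise ConfigError(
                f"unknown instrument {self.name!r}; expected one of {INSTRUMENT_NAMES}"
            )
        if not (self.norm_sd > 0):
            raise ConfigError(f"instrument {self.name}: norm_sd must be > 0")


def assign_trait_group(score: float, instrument: TraitInstrument) -> TraitGroup:
    """Map a total trait score onto its subgroup under the instrument norms.

    Bands are half-open: ``score == mean + 2·SD`` is MAP, not BAP.
    """
    if instrument is None:
        raise ConfigError("instrument norms are required to assign a trait group")
    if not math.isfinite(score):
        raise InputError(f"non-finite trait score {score!r}")
    mean, sd = instrument.norm_mean, instrument.norm_sd
    if score >= mean + 3 * sd:
        return TraitGroup.NAP
    if score >= mean + 2 * sd:
        return TraitGroup.MAP
    if score >= mean + 1 * sd:
        return TraitGroup.BAP
    return TraitGroup.AVERAGE


@dataclass
class Individual:
    individual_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"  # female / male / unknown
    diagnosis: Diagnosis = Diagnosis.UNKNOWN
    trait_score: float | None = None
    instrument: TraitInstrument | None = None
    trait_group: TraitGroup | None = None

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    def with_trait(self, score: float, instrument: TraitInstrument) -> "Individual":
        return replace(
            self,
            trait_score=score,
            instrument=instrument,
            trait_group=assign_trait_group(score, instrument),
        )


@dataclass(frozen=True)
class Trio:
    father: Individual
    mother: Individual
    child: Individual


@dataclass
class Family:
    family_id: str
    members: dict[str, Individual] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        for ind in self.members.values():
            if ind.family_id != self.family_id:
                raise PedigreeError(
                    f"member {ind.individual_id} has family_id {ind.family_id}, "
                    f"expected {self.family_id}"
                )
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in self.members:
                    raise PedigreeError(
                        f"family {self.family_id}: parent {pid} of "
                        f"{ind.individual_id} not found"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # an individual must never be its own ancestor
        state: dict[str, int] = {}  # 0=visiting, 1=done

        def visit(iid: str) -> None:
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                raise PedigreeError(
                    f"family {self.family_id}: pedigree cycle through {iid}"
                )
            state[iid] = 0
            ind = self.members[iid]
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    visit(pid)
            state[iid] = 1

        for iid in self.members:
            visit(iid)

    @property
    def diagnosed(self) -> set[str]:
        return {
            i for i, m in self.members.items() if m.diagnosis is Diagnosis.DIAGNOSED
        }

    @property
    def non_autistic(self) -> set[str]:
        """Strictly non-autistic members: excludes suspected and unknown."""
        return {
            i for i, m in self.members.items() if m.diagnosis is Diagnosis.NON_AUTISTIC
        }

    @property
    def is_highly_multiplex(self) -> bool:
        """True iff ≥3 members carry an autism diagnosis (ascertainment rule)."""
        return len(self.diagnosed) >= 3


def enumerate_trios(family: Family, genotyped_ids: Iterable[str]) -> list[Trio]:
    """All (father, mother, child) triples fully genotyped, ordered by child id.

    A multi-generation family yields trios at every level: a parent who is
    also the child of genotyped grandparents appears as the child of a
    second trio.
    """
    genotyped = set(genotyped_ids)
    trios = []
    for child_id in sorted(family.members):
        child = family.members[child_id]
        if child.father_id is None or child.mother_id is None:
            continue
        if {child_id, child.father_id, child.mother_id} <= genotyped:
            trios.append(
                Trio(
                    father=family.members[child.father_id],
                    mother=family.members[child.mother_id],
                    child=child,
                )
            )
    return trios


# ---------------------------------------------------------------------------
# Loading

_SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}
_DIAGNOSIS_TOKENS = {
    "diagnosed": Diagnosis.DIAGNOSED,
    "suspected": Diagnosis.SUSPECTED,
    "non_autistic": Diagnosis.NON_AUTISTIC,
    "unknown": Diagnosis.UNKNOWN,
    # plain PLINK phenotype coding, for 6-column files
    "2": Diagnosis.DIAGNOSED,
    "1": Diagnosis.NON_AUTISTIC,
    "0": Diagnosis.UNKNOWN,
    "-9": Diagnosis.UNKNOWN,
}


def load_instrument_norms(source: Mapping | str | Path) -> dict[str, TraitInstrument]:
    """Build instruments from a mapping or a YAML file ``name -> {mean, sd}``."""
    if not isinstance(source, Mapping):
        import yaml

        with open(source) as fh:
            source = yaml.safe_load(fh)
    norms = {}
    for name, spec in source.items():
        norms[name] = TraitInstrument(
            name=name, norm_mean=float(spec["mean"]), norm_sd=float(spec["sd"])
        )
    return norms


def read_ped(path: str | Path) -> list[Individual]:
    """Parse a PLINK-style PED, optionally extended with a 7th diagnosis column.

    Columns: family, individual, father, mother, sex (1/2/0), phenotype,
    [diagnosis].  The 7th column carries the study's four-state diagnosis
    (diagnosed / suspected / non_autistic / unknown); without it, the
    standard phenotype column is interpreted (2=diagnosed, 1=non_autistic).
    """
    individuals: list[Individual] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) not in (6, 7):
                raise InputError(f"{path}:{lineno}: expected 6 or 7 columns")
            fam, iid, fid, mid, sex, pheno = fields[:6]
            dx_token = fields[6] if len(fields) == 7 else pheno
            if iid in seen:
                raise InputError(f"{path}:{lineno}: duplicate individual id {iid}")
            seen.add(iid)
            dx = _DIAGNOSIS_TOKENS.get(dx_token.lower())
            if dx is None:
                raise InputError(
                    f"{path}:{lineno}: unknown diagnosis token {dx_token!r}"
                )
            individuals.append(
                Individual(
                    individual_id=iid,
                    family_id=fam,
                    father_id=None if fid == FOUNDER else fid,
                    mother_id=None if mid == FOUNDER else mid,
                    sex=_SEX_CODES.get(sex, "unknown"),
                    diagnosis=dx,
                )
            )
    return individuals


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read the per-individual trait table (CSV or TSV, sniffed)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"individual_id", "instrument", "score"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: trait table missing columns {sorted(missing)}")
    df["individual_id"] = df["individual_id"].astype(str)
    return df


def load_cohort(
    ped_source: str | Path,
    trait_source: str | Path | None = None,
    instrument_config: Mapping | str | Path | None = None,
    diagnosis_table: str | Path | None = None,
) -> dict[str, Family]:
    """Assemble families from PED + trait table + instrument norms.

    ``diagnosis_table`` optionally overrides/extends diagnosis status from a
    two-column side table (individual_id, diagnosis) for 6-column PEDs.
    """
    individuals = {ind.individual_id: ind for ind in read_ped(ped_source)}

    if diagnosis_table is not None:
        side = pd.read_csv(diagnosis_table, sep=None, engine="python")
        for _, row in side.iterrows():
            iid = str(row["individual_id"])
            if iid not in individuals:
                raise InputError(f"diagnosis table references unknown id {iid}")
            individuals[iid].diagnosis = Diagnosis(str(row["diagnosis"]))

    if trait_source is not None:
        if instrument_config is None:
            raise ConfigError("instrument norms required when trait scores are given")
        norms = load_instrument_norms(instrument_config)
        traits = read_trait_table(trait_source)
        for _, row in traits.iterrows():
            iid = str(row["individual_id"])
            if iid not in individuals:
                raise InputError(f"trait table references unknown individual {iid}")
            name = str(row["instrument"])
            if name not in norms:
                raise ConfigError(f"no norms configured for instrument {name!r}")
            individuals[iid] = individuals[iid].with_trait(
                float(row["score"]), norms[name]
            )

    families: dict[str, Family] = {}
    by_family: dict[str, dict[str, Individual]] = {}
    for ind in individuals.values():
        by_family.setdefault(ind.family_id, {})[ind.individual_id] = ind
    for fam_id, members in by_family.items():
        fam = Family(family_id=fam_id, members=members)
        if not fam.is_highly_multiplex:
            log.warning(
                "family %s has only %d diagnosed members (<3): not highly multiplex",
                fam_id,
                len(fam.diagnosed),
            )
        n_unknown = sum(
            1 for m in members.values() if m.diagnosis is Diagnosis.UNKNOWN
        )
        if n_unknown:
            log.info("family %s: %d members with unknown diagnosis", fam_id, n_unknown)
        families[fam_id] = fam
    return families
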