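# Methods

## The analysis model

`famseg` operates on called, annotated short variants from multiplex
pedigrees; it performs no alignment, calling or annotation itself. The unit
of analysis is the family: each family's multi-sample genotypes are
filtered and tested independently, and cohort-level summaries (gene lists,
Venn classification, enrichment) aggregate per-family results over
distinct genes.

### Trait subgroups

Autistic-trait scores are interpreted relative to instrument-specific
normative means and SDs. Bands are half-open, closed at the lower edge:
a score of exactly μ+2σ is MAP, not BAP. This convention is a package
decision — band definitions of the form "between 1 and 2 SD" do not
specify the boundaries — and guarantees the four bands partition the score
line, so assignment is single-valued and monotone in the score. Norms are
**required configuration**: published norm samples differ by instrument
(adult/adolescent/child AQ, Q-CHAT) and revision, so no defaults are
baked in. All four instruments map onto the same SD-band logic; how
toddler Q-CHAT scores relate to adult-derived bands is an open modelling
question the package inherits rather than resolves.

### Diagnosis status

Diagnosis is four-valued: diagnosed, suspected, non-autistic, unknown.
Suspected members (recruited but never formally assessed) are first-class:
they neither count toward the "shared by ≥ 2 diagnosed" rule nor veto via
the "absent in non-autistic members" rule, and they are excluded from both
rows of the enrichment table. Unknown-status and unscored members likewise
neither count nor veto, and are logged.

### Segregation rules

For a biallelic site, a family's members partition into support-passing
carriers (het/hom-alt, depth ≥ 10, het alt fraction ≥ 33%), weak carriers
(alt genotype failing support), non-carriers (hom-ref) and missing.
Hom-alt genotypes count as carriers (dominant-model reading).

* **Diagnosis rule**: ≥ 2 diagnosed support-passing carriers, and no
  non-autistic member among *any* non-missing alt carriers. The veto
  deliberately ignores read support: a weakly supported alt genotype in an
  unaffected member is still evidence against dominant segregation,
  whereas counting such calls *toward* sharing would inflate hits.
* **Trait rule**: the label is the minimum trait band over scored
  support-passing carriers, provided there are ≥ 2 of them and none is in
  the AVERAGE band. This is equivalent to the per-band formulation
  ("present in ≥ 2 members of band L or higher and absent below L",
  taking the most stringent qualifying L), an equivalence the test suite
  verifies by brute-force enumeration of all carrier subsets on small
  families.

Both rules run on the same post-filter variant set; in `both` mode a
variant can carry a combined label (e.g. `NAP/Diagnosis`).

### De novo filter

Applied per trio to jointly represented genotypes, with five gates (strict
inequalities as stated): depth > 20 in all three members; child alt reads
≥ 8; child alt fraction > 0.40 with the genotype call heterozygous when
available (no upper fraction bound is enforced); each parent's alt
fraction < 0.05 — "absent in parents" is read per-parent, not pooled;
MAF ≤ 1% (inclusive, unlike the inherited filter's strict < 1%; both are
configurable) with a disruptive class, where splicing qualifies here but
not in the inherited filter; and gene pLI ≥ 0.9 (genes missing from the
constraint table fail). Upstream trio callers are assumed strictly more
permissive than these gates, so the filter's outcome does not depend on
the caller. A candidate inherits its report label from its carrier child
(diagnosis status and trait band), which is how de novo genes enter the
cross-family approach comparison.

### Gene constraint

The pLI threshold is ≥ 0.9 throughout (source descriptions vary between
"greater than" and "greater than or equal"; the inclusive reading is
adopted and configurable). The default constraint mode is the **union**
pLI ≥ 0.9 ∨ LOEUF < 0.37: the two metrics describe one constrained-gene
set and the permissive reading is the safer default; intersection and
single-metric modes are available. Missing MAF passes the rarity gate by
default — prioritised variants absent from gnomAD are the most interesting
class, so absence must not disqualify.

### Tiers and enrichment

Tier precedence is 1 > 2 > 3 over named source lists, matched on
uppercased symbols with no alias resolution (HGNC alias mapping is an
extension point). Real database snapshots are not bundled for licensing
and versioning reasons; the shipped `*.synthetic.txt` lists are stand-ins
containing exactly the worked-example genes.

The enrichment statistic is the uncorrected Pearson χ² on the 2×2
carrier-by-diagnosis table with an upper-tail p on 1 df. No continuity
correction is applied by default: on the study table (50, 24, 11, 23) the
uncorrected statistic is 11.75 while Yates gives ≈ 10.4, and only the
former reproduces the published value; a `continuity_correction` flag is
provided. No Fisher-exact fallback is implemented (single pre-specified
test; documented extension). The odds ratio is reported when no cell is
zero.

## The synthetic-data generator

The generator emulates the ascertainment and measurement structure of a
highly multiplex cohort, not its linkage structure:

* **Pedigrees**: 21 nuclear families by default (two or three
  generations), with an explicit `STUDY_PLAN` reproducing the motivating
  cohort exactly — 112 members, 76 diagnosed, four suspected, ten families
  with ≥ 4 diagnosed and one under-recruited family with only two.
* **Traits**: scores on a synthetic adult-AQ scale (μ = 20, σ = 5, range
  0–50) drawn from Normal(μ + 2.6σ, 0.9σ) for diagnosed members and
  Normal(μ + 0.6σ, σ) for their relatives, truncated to the instrument
  range. The offsets were chosen once as plausible for a multiplex cohort
  in which relatives score above the general population; they yield a
  NAP/MAP/BAP-heavy cohort of the right general shape.
* **Planted variants** are placed heterozygous on a founder and
  transmitted by honest Mendelian sampling, **rejection-sampled** until
  the carrier pattern satisfies the target rule (≥ 2 diagnosed carriers
  and no non-autistic carrier for diagnosis plants; ≥ 2 elevated-band
  carriers with no sub-BAP carrier for trait plants, the achieved level
  being the carriers' minimum band). Plants are never painted onto
  phenotypes, so they obey the same transmission law as background
  variation; an unsatisfiable plant raises a documented error after a
  bounded number of retries.
* **De novo plants** go to one diagnosed trio child with hom-ref parents,
  with read evidence rejection-sampled into the filter's acceptance
  region.
* **Noise variants** transmit honestly from random founders with an
  optional genotype-error rate ε (a flip to one of the other two genotype
  states with probability ε); their annotations pass the damaging +
  constraint gates only at a configurable rate (0 by default, i.e. a
  guaranteed-failing synonymous/common/unconstrained combination).
* **Read evidence**: depth ~ Poisson(35); alt reads ~ Binomial(depth, f)
  with f = 0.5 for het, 0.005 for hom-ref, 0.995 for hom-alt. Planted
  carriers' evidence is resampled until it passes the relevant support
  gates, which is what makes exact planted recovery a designed property
  rather than a statistical accident.
* One variant per synthetic gene, with positions drawn from a fixed gene
  map, so gene joins are exact. The whole bundle is byte-identical under a
  fixed seed; under ε > 0 the generator also returns the analytic
  expectation and variance of trio Mendelian-violation counts (sum of
  per-trio violation probabilities from the 27-outcome error enumeration,
  independence approximation across overlapping trios).

What the generator does **not** emulate — linkage disequilibrium,
recombination, realistic allele-frequency spectra, sequencing artefacts
correlated across sites, assortative mating — bounds what passing tests
show: they validate the filtering, segregation and accounting logic under
the stated models, not robustness to real-data artefacts.

## Worked-example fixture

The packaged hit table transcribes the published summary of prioritised
variants (43 records over 40 genes once a two-family row is split). Two
transcription decisions are recorded in the file header: a garbled
trait/diagnosis label on one de novo row is stored as diagnosis-only,
consistent with the published Venn counts; and the two-family row is split
with an arbitrary family-to-band assignment that no computed count depends
on. The published prose also says "eight" Tier-1 diagnosis-only genes
while listing nine; the package reproduces the table (nine). A
deterministic inverse-constructor builds a full cohort bundle (PED,
traits, VCF, annotation/constraint tables, tier lists) realising one
minimal genotype configuration per row — carriers always include the
transmitting mother, keeping genotypes Mendelian-consistent and keeping
inherited variants out of the de novo filter — and the pipeline reproduces
every row's label from it, end to end.

The published 2×2 enrichment counts (74 diagnosed, 34 non-diagnosed,
N = 108 after excluding four suspected) are taken as printed; note they
imply two fewer diagnosed members than the participant totals, a
discrepancy in the source left as-is.

## Numerical and engineering choices

* Coordinates are 1-based VCF convention; multi-allelic records are
  decomposed per alternate allele (other alternates count as reference
  for the decomposed site, AD split per allele); no left-alignment or
  liftover. Annotation joins by exact (chrom, pos, ref, alt), with
  dash-style indel keys (`C/-`) accepted and normalised against anchored
  VCF representations. Unmatched genotype sites are dropped with a logged
  count.
* Missing evidence fails closed everywhere (absent depth/AD fails read
  support; absent trio evidence fails the de novo gates); missing MAF is
  the documented exception.
* The χ² is computed in closed form and cross-checked in tests against an
  independent implementation; a zero margin raises an undefined-test
  error rather than returning 0.
* Analysis stages are deterministic by contract; all randomness lives in
  the generator behind a single seed. Report rows are ordered by (tier,
  gene, family, position).
* Default simulation scale (≈ 112 members, ≈ 150 sites) keeps a full
  simulate-and-analyse cycle under a few seconds while exercising every
  pipeline stage.

## Limitations

* No linkage/LOD computation, phasing, IBD inference or compound-het
  modelling; the segregation rules are presence/absence heuristics.
* No somatic/mosaic modelling in the de novo filter and no upper bound on
  the child alt fraction.
* Deleteriousness predictions are consumed, never computed; annotation
  quality bounds result quality.
* Tier assignment is only as good as the supplied gene lists; symbol
  matching is verbatim (uppercased) with no alias resolution.
* The enrichment test treats carriers as independent, ignoring family
  clustering — as in the source analysis; a clustered or exact test is an
  extension point.
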