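# Methods

## Model and scope

`amefreq` estimates how common carriers of a rare autosomal recessive
disorder are — concretely, apparent mineralocorticoid excess (AME) from
inactivating *HSD11B2* variants — using only per-variant allele counts from
a large reference cohort (a gnomAD-style browser export). The unit of
analysis is the variant row, never the individual: no genotypes,
coordinates or transcripts are consumed, which is why the package reads
flat TSV tables rather than VCF.

The estimator chain is:

1. qualify variants as potentially disease-causing (three evidence arms,
   two tiers);
2. sum allele counts of the qualifying set and divide by the number of
   individuals to get the carrier frequency `p = ΣAC / N`;
3. square up to a biallelic (affected) genotype frequency under
   Hardy–Weinberg equilibrium.

Assumptions inherited from this design: variants are rare and biallelic,
so one allele ≈ one carrier and compound heterozygosity across the
qualifying set is negligible at the estimation scale; mating is random
with no selection or inbreeding adjustment; the allele number per variant
is taken as 2N per group (coverage differences are not modelled);
penetrance is complete. Consanguineous subpopulations — where most AME
cases are actually reported — violate random mating, so the prevalence
estimates are population-average figures, not clinical risk figures.

## Variant qualification

Arms (a variant may satisfy several; tiers are sets, not sums):

- **ClinVar arm** — classification in {P, LP, P/LP}. "Conflicting
  classifications" is its own category and does not qualify.
- **Literature arm** — curated flag for variants reported in an AME
  patient. A ClinVar benign/likely-benign call vetoes this arm; VUS and
  conflicting calls do not (a VUS qualifies exactly when
  literature-reported).
- **In-silico arm** — by consequence class: nonsense and frameshift
  qualify unconditionally; in-frame indels need CADD > 20 and a damaging
  SIFT-indel verdict; splice-site variants need SpliceAI ≥ 0.8, CADD > 20
  and |Pangolin| > 0.2; missense need CADD > 20, SIFT < 0.05,
  PolyPhen2 > 0.85 and REVEL > 0.75; anything else fails. Every
  inequality is strict except SpliceAI's, which is inclusive — the
  boundary tests pin each direction. A missing required score fails the
  rule: variants are never qualified on evidence they lack.

**Strict tier** = ClinVar ∪ literature (higher confidence).
**Liberal tier** = strict ∪ in-silico. Strict ⊆ liberal by construction,
and the suite property-tests this on arbitrary inputs.

Benign/likely-benign exclusion is applied globally (all three arms) by
default, not just inside the literature arm: an in-silico-passing B/LB
variant contradicts its curated status, and the global reading is the
safer one. `QualificationConfig(exclude_blb=False)` restores the literal
per-arm reading. All thresholds are configurable; the defaults above are
the standard cutoffs used in curation practice.

Consequence classes come from the table's `consequence` column when
present, otherwise from deliberately shallow HGVS pattern rules (`fs` →
frameshift, terminal `Ter` substitution → nonsense, `del`/`dup`/`ins` →
in-frame indel, simple substitution → missense, cDNA-only intronic offset
→ splice site). A full HGVS grammar buys nothing here because only the
class is needed; the rules reproduce the curated consequence of all 32
packaged reference variants.

## Estimation

Carrier frequency is **alleles per individual**, `p = ΣAC / N`, not
divided by 2N — this matches how the reference tables define within-group
carrier frequency, and for rare variants it equals the carrier proportion
to first order. Its standard error is the binomial `sqrt(p(1−p)/N)`,
which agrees with a parametric bootstrap over 2N Bernoulli alleles within
5% relative error for p ≥ 1e-4, N ≥ 1e5 (tested; the two differ by a
factor `(1−q)/(1−2q)` under the square root, negligible in this regime).

Prevalence under Hardy–Weinberg is implemented in two conventions, and
every output names the one used:

- `cf_squared` (default): prevalence = p², delta-method SE = 2·p·SE(p);
- `half_cf_squared`: prevalence = (p/2)², SE = (p/2)·SE(p) — the textbook
  q² with allele frequency q = p/2. Exactly one quarter of the default,
  property-tested as such.

The default is `cf_squared` because it is the convention under which the
published headline prevalence figures for this disorder are internally
consistent with their published carrier frequencies (24.5e-5 → 0.6 per
1e7; 82.6e-5 → 6.8 per 1e7), whereas (p/2)² yields 0.15 and 1.7. The
package takes no position beyond arithmetic consistency: both conventions
are first-class, and the discrepancy is documented rather than hidden.

Stratified estimates use each group's own allele counts and N; the global
estimate uses the total N including groups excluded from stratification
(the Amish group, n = 456, is excluded from per-group output via the
panel's `excluded` flag, not re-derived). Reported values are scaled per
100,000 (carrier frequency) and per 10,000,000 (prevalence) and rounded
to one decimal, ties away from zero (131.97 → 132.0, 2.881 → 2.9); raw
proportions are always retained in the JSON output, and rounding happens
only at the reporting boundary.

The enrichment scan flags (variant, group) pairs whose within-group
carrier frequency is at least `min_ratio` (default 2.0) times the
variant's global carrier frequency, with at least `min_ac` (default 1)
alleles in the group. The published enrichment table states no numeric
inclusion criterion, so the ratio is an explicit, configurable parameter;
the packaged table is used to validate the frequency *values*, not flag
membership.

## Synthetic cohorts

The generator emulates exactly the statistical structure the estimator
assumes, at count level:

- allele counts per variant and group are `Binomial(2·N_group, q)`,
  independent across variants and groups — no linkage, shared haplotypes,
  genotype-level data, sequencing error or consanguinity;
- true per-group allele frequencies are capped at 0.01 (rare-variant
  regime; the estimator is not meant for common alleles);
- in-silico scores are drawn from consequence- and pathogenicity-
  conditional distributions (pathogenic missense CADD ~ Normal(28, 3)
  truncated at 0, benign ~ Normal(10, 5); beta distributions for the
  unit-interval scores with pathogenic mass beyond the thresholds).
  These reproduce the qualitative separation seen in curated databases —
  P/LP-labelled variants have higher CADD than B/LB — without claiming
  realism;
- ClinVar labels are drawn from a categorical conditional on true
  pathogenicity (imperfect on purpose: by default a truly pathogenic
  variant is VUS or absent more often than P/LP), and a pathogenic
  variant is literature-reported with probability
  `literature_sensitivity` (default 0.5).

Seeding: one root `numpy.random.SeedSequence` per config is spawned into
one child stream per variant, so tables are reproducible and independent
of iteration order; identical configs give byte-identical TSVs.

Because truth is known in closed form (E[AC/N] = 2q per variant and
group, additive over variants), the suite checks parameter recovery:
across 200 seeded cohorts at N = 500,000 with true carrier frequency 50
per 100,000, the interval CF ± 1.96·SE covers the truth ≥ 90% of the
time, and the mean absolute error matches the binomial scale. Passing
these tests validates the estimator's arithmetic and calibration under
its own model; it says nothing about annotation quality, ancestry
misclassification or coverage artefacts in real exome data.

## Numerical and degenerate-input choices

- Empty qualifying set: carrier frequency 0 with SE 0; prevalence 0.
- Carrier frequency above 1 allele per individual is rejected — outside
  the rare-disease regime the quantity stops being a carrier proportion.
- Missing score cells are empty strings in TSV and `None` in memory;
  zero is always a real score.
- Malformed rows are collected and reported with row numbers in one
  validation error rather than failing on the first.
- Packaged reference tables are SHA-256-checksummed at load.
- Rounding is half-away-from-zero via `decimal`, applied once at the
  reporting boundary.

## Problem sizes

The packaged analyses are desk-scale (32 + 31 variants, arithmetic over
ten groups) and run in well under a second. The statistical validation
uses 200 simulated cohorts of 2 variants at N = 500,000 and
4,000-replicate bootstrap checks at N up to ~8e5 — sizes chosen so the
Monte-Carlo error of each check is several times smaller than the
tolerance it asserts, while the whole suite stays in the seconds range.

## Known limitations

- Carrier frequency aggregates alleles across variants; two qualifying
  alleles in one individual are counted as two carriers. At the
  frequencies involved (~1e-4) the bias is second-order.
- No confidence intervals beyond ±SE; no population-structure,
  consanguinity or penetrance modelling.
- The literature flag is an input (a curated list), not something the
  package derives; classification drift in ClinVar moves the strict tier.
- The in-silico arm inherits the predictors' blind spots (e.g. deep
  intronic or regulatory variants are invisible to it).
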