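# amefreq

Carrier-frequency and Hardy–Weinberg prevalence estimation for **apparent
mineralocorticoid excess (AME)** — the rare autosomal recessive hypertension
syndrome caused by biallelic inactivating variants in *HSD11B2* — from
gnomAD-style per-variant allele-count tables.

The package is for medical geneticists and genetic epidemiologists who want
population-scale estimates of how common a recessive disorder's carriers and
affected genotypes are, stratified by genetic ancestry, when all they have is
a per-variant annotation table (allele counts, ClinVar classifications,
in-silico scores) rather than individual-level genotypes.

## What it computes

1. **Variant qualification** — each variant is tested against three evidence
   arms: ClinVar pathogenic/likely-pathogenic (P/LP); reported in a patient
   in the curated literature (a benign/likely-benign ClinVar call vetoes
   this, a VUS does not); or in-silico deleteriousness (all nonsense and
   frameshift variants; in-frame indels with CADD > 20 and a damaging
   SIFT-indel verdict; splice-site variants with SpliceAI ≥ 0.8, CADD > 20
   and |Pangolin| > 0.2; missense variants with CADD > 20, SIFT < 0.05,
   PolyPhen2 > 0.85 and REVEL > 0.75). Arms 1–2 define the **strict** tier;
   adding arm 3 gives the **liberal** tier.

2. **Carrier frequency** — the combined allele count of qualifying variants
   divided by the number of sequenced individuals, `p = ΣAC / N`, with
   binomial standard error `SE = sqrt(p(1−p)/N)`; computed globally and
   within each ancestry group.

3. **Prevalence** — under Hardy–Weinberg equilibrium (random mating, no
   selection), with delta-method standard errors. Two conventions are
   implemented and always named in the output: `cf_squared` (prevalence
   = p², the default) and `half_cf_squared` (prevalence = (p/2)², exactly
   one quarter of the former); see `docs/methods.md` for why both exist.

4. **Ancestry enrichment** — per-variant within-group carrier frequencies
   and a configurable scan flagging (variant, group) pairs whose
   within-group frequency exceeds the global one by a chosen ratio.

5. **Synthetic cohorts** — a count-level generative model (binomial allele
   counts per group, consequence- and pathogenicity-conditional scores,
   noisy ClinVar labels) with closed-form truth, so the whole pipeline is
   testable without downloading anything.

## Worked example

The package ships the curated *HSD11B2* reference tables (32 ClinVar- or
literature-supported variants, the ancestry-enrichment table, and the ten
gnomAD v4.1 ancestry-group sample sizes totalling 807,162 individuals):

```python
import amefreq as af

panel = af.load_fixture("panel")      # 807,162 individuals, 10 groups
table1 = af.load_fixture("table1")    # 32 curated variants

est = af.CarrierFrequencyEstimator(panel=panel, tier="strict").fit(table1)
print(est.summary_["strict"], est.combined_allele_count_)
print(af.round_half_away(est.carrier_frequency_ * 1e5, 1),
      af.round_half_away(est.prevalence_ * 1e7, 1))
```

prints

```
32 198
24.5 0.6
```

i.e. all 32 curated variants qualify under the strict rules, their combined
allele count is 198, the global carrier frequency is **24.5 per 100,000
individuals**, and the implied disease prevalence is **0.6 per 10,000,000**.
Stratifying the enrichment table the same way gives the Middle Eastern
group's strict-tier carrier frequency of **132.0 per 100,000** (4 alleles in
3,031 individuals):

```python
table2 = af.table2_records()
results = af.qualify_variants(table2)
mid = [e for e in af.stratified_estimates(table2, results, panel, "strict")
       if e.scope == "mid"][0]
print(mid.cf_per_1e5)   # 132.0
```

The same pipeline is available from the shell:

```sh
amefreq estimate --variants variants.tsv --panel panel.tsv --out-dir out/
amefreq simulate --config sim.yaml --seed 7 --out-dir sim/
```

## Layout

- `amefreq.schema` / `amefreq.io` — variant-table and panel data model, TSV
  reading/writing, validation
- `amefreq.hgvs` — shallow consequence inference from HGVS strings
- `amefreq.qualify` — the three evidence arms and tier assignment
  (`VariantQualifier` transformer)
- `amefreq.estimate` — frequencies, prevalences, stratification, enrichment
  (`CarrierFrequencyEstimator`, `EnrichmentScanner`)
- `amefreq.simulate` — synthetic cohort generator with known truth
- `amefreq.report` — CADD-by-classification numeric summaries
- `amefreq.cli` — `amefreq qualify | estimate | enrich | simulate | report`
- `amefreq.fixtures` — the packaged, checksummed reference tables
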