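# lektimap

Genotype–phenotype analysis of *SPINK5* variants in Netherton syndrome.

Netherton syndrome (NS) is a rare autosomal-recessive ichthyosis caused by
biallelic loss-of-function variants in *SPINK5*, which encodes LEKTI, a
1064-residue serine protease inhibitor built from fifteen Kazal-type
domains. Clinical severity ranges from mild scaling to death in infancy,
and where a variant falls along the protein appears to matter. `lektimap`
is a reusable, tested pipeline for clinicians and geneticists who curate NS
case collections and want to ask, reproducibly: *does variant location
predict phenotype?*

The pipeline:

1. **Variant mapping** — parses HGVS cDNA strings on transcript
   NM_006846.4 (CDS 3195 nt), tolerating the stray spaces common in print
   (`c. 995delT`). Each variant is anchored to its 5′-most coding base,
   assigned the codon ⌈anchor/3⌉, a transcript half (bases 1–1598 → 5′
   half, 1599–3195 → 3′ half), one of the 15 LEKTI domains (inclusive
   amino-acid ranges, D1 = AA 28–66 … D15 = AA 987–1048), one of 5 domain
   regions (D1–5, D6, D7, D8–9, D10–15), and a mutation-type class.
2. **Genotype coding** — per-allele values (half ∈ {1,2}; domain number
   1–15; DomainR-5 indicator; in-domain indicator) and their two-allele
   products `halfx`, `domnum_x`, `d5x`, `indom_x` as covariates; for
   homozygous-only analyses the single-allele value is used.
3. **Association** — binary logistic regression of each phenotype on one
   coded covariate with age in years as a covariate (all terms entered
   simultaneously), reported as OR = exp(β) with Wald 95% CI
   exp(β ± 1.96·SE); plus a 2×2 chi-square test of fatal-variant
   homozygosity against death during infancy. A *fatal variant* is one
   with ≥1 homozygous carrier who died in infancy (<1 year).
4. **Simulation** — a seeded synthetic-cohort generator whose defaults
   reproduce the published 162-patient cohort's marginals (324 alleles;
   region mix 126:12:14:23:107:42; type mix 99:93:85:33:7:6:1; 89/162
   homozygotes; published tri-state missingness), used for power and
   parameter-recovery studies.

## Worked example

```python
import lektimap as lm

# 1. annotate a splice-site variant (note the tolerated spaces)
a = lm.annotate_variant(lm.parse_hgvs("c. 1887 + 1G>A"))
# c.1887+1G>A: half=2 codon=629 domain=10 region=DomainR-5 type=splicing

# 2. fatal-variant mortality analysis on the built-in literature cohort
cohort = lm.fatal_variant_demo_cohort()
fatal = lm.identify_fatal_variants(cohort)
res = lm.fatal_contingency(cohort, fatal)
# fatal variants: c.1111C>T, c.1431-12G>A, c.153delT, c.1887+1G>A, c.995delT
# 2x2 (rows hom/het x died/survived): [[14, 4], [0, 12]]
# chi2=17.500 df=1 p=2.87e-05

# 3. simulate a cohort with a protective 5'-half effect and refit it
cfg = lm.SimulationConfig(
    seed=7, n_patients=500,
    phenotype_models={**lm.simulate.default_phenotype_models(),
        "failure_to_thrive": lm.PhenotypeModel(intercept=1.2,
                                               betas={"halfx": -0.5})},
    missingness={p: 0.0 for p in lm.PHENOTYPES})
records, truth = lm.simulate_cohort(cfg)
table, drops = lm.build_dataset(records, "halfx", "failure_to_thrive")
fit = lm.fit_logistic(table, "failure_to_thrive", "halfx")
# n=500 beta=-0.544 OR=0.580 (95% CI 0.499-0.675) p=0.0000
```

The annotation output reads: the variant's coding anchor 1887 lies in the
3′ half (code 2), codon 629 falls in domain 10 and hence DomainR-5, and the
`+1` intronic offset forces the splicing class. In the mortality table all
14 infant deaths sit in the homozygous row — heterozygous carriers of a
fatal allele survived — and the chi-square soundly rejects independence
(p < 0.001). In the simulation, the fitted odds ratio 0.58 < 1 recovers the
generating coefficient β = −0.5 (OR ≈ 0.61): variants kept in the 5′ half
(lower `halfx`) raise the odds of failure to thrive.

The same steps are available from a shell:

```sh
lektimap annotate c.153delT c.1887+1G>A --out annotated.tsv
lektimap fatal --demo --out fatal.json
lektimap simulate --n 500 --seed 7 --out cohort.tsv
lektimap report --cohort cohort.tsv --out-dir report/
lektimap recover --seed 1 --replicates 200 --out recovery.json
```

Exit codes: 0 success, 2 validation error, 3 statistics error. Cohort files
are plain TSV/CSV (see `docs/methods.md` for the schema); reports are
deterministic TSV + JSON with full provenance.

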