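# Methods

## Coordinate model

All variants are interpreted on the coding sequence (c. coordinates) of
*SPINK5* transcript NM_006846.4: 3195 CDS bases = 1064 residues + stop.
The 5′/3′ split is taken on CDS coordinates with the boundary at base 1598
inclusive in the 5′ half; this is the only reading under which the stated
3195-bp span equals the CDS length and the recurrent fatal variants land
in their published halves (c.1431 → half 1, c.1887 → half 2).

Anchoring rules (applied uniformly to half, codon and domain assignment):

* intronic positions (`c.1431-12`, `c.1887+1`) anchor to the coding base
  named in the HGVS string; the offset is ignored for location but forces
  the splicing mutation class;
* multi-base edits (`c.2472_2473delAG`, ranges with intronic ends) anchor
  to the 5′-most affected coding base. This is deterministic and matches
  the single-position convention of published variant tables; large events
  spanning many domains are excluded upstream by the curation filters, so
  the rule only ever moves an assignment by a few bases;
* the affected codon is ⌈anchor/3⌉; the stop codon (1065) is representable
  but belongs to no domain.

Domain ranges are inclusive on both ends (D1 = AA 28–66 … D15 =
AA 987–1048, 909 in-domain residues, 155 non-domain residues of 1064).
Regions partition the domains as {1–5}, {6}, {7}, {8–9}, {10–15}. Both
tables ship as a JSON resource and can be replaced by any table with the
same schema, so the machinery generalizes to other multidomain proteins.

Nonsense/missense discrimination needs the reported protein consequence
(the package ships no reference sequence and never translates); a coding
substitution without one is the explicit state `unclassified-substitution`,
never silently binned.

## Cohort schema and curation

Cohort files are UTF-8 TSV/CSV with columns `patient_id`, `source`,
`age_years`, `allele1_cdna`, `allele2_cdna`, optional `allele1_protein` /
`allele2_protein`, `large_event_flag`, optional `exclude_reason`,
`died_in_infancy`, and one tri-state column (`+`/`-`/`NA`) per phenotype:
ilc, erythroderma, hair_shaft_anomalies, failure_to_thrive,
recurrent_infection, hypernatremia, angioedema, urticaria, asthma.

`NA` means *no clear clinical record*, which is distinct from recorded
absence; all models are complete-case per phenotype. Both alleles are
mandatory (single-variant patients are a schema error, mirroring the
study-inclusion requirement of confirmed biallelic genotypes). Zygosity is
derived: equal normalized HGVS strings ⇔ homozygous.

Executable exclusion filters: curator-flagged rows (`exclude_reason`
covers judgments such as incorrect mutation assessment that software
cannot recompute), large deletions/duplications that cannot be assigned to
a domain, and duplicate `patient_id`s (first occurrence kept). Filtering
is idempotent and reported per criterion.

`died_in_infancy` is its own tri-state outcome; infancy is taken as age at
death < 1 year. The threshold is a package decision — sources imply a
one-year horizon but do not define it numerically.

## Genotype coding

Per-allele values: half ∈ {1, 2}; domain number ∈ 1..15 (undefined outside
domains); DomainR-5 indicator; in-domain indicator. Two-allele covariates
are the products `halfx` ∈ {1, 2, 4}, `domnum_x` ∈ 1..225, `d5x`,
`indom_x` ∈ {0, 1}. Products are commutative and alleles are canonically
ordered, so coding is invariant to allele order. Because a non-domain
allele has no domain number, `domnum_x` is missing for such genotypes and
the patient drops out of that analysis (counted in the drop report) — a
product with an undefined ordinal factor has no meaning, and complete-case
omission is the conservative choice. Both `domnum_x` and `indom_x` are
exposed because "variants in domains" can be read as either coding; every
result records which covariate was used. Homozygous-only analyses use the
single-allele value (the product would merely square it). Covariates enter
the model as supplied, uncentered and unscaled.

## Association model

For each phenotype × covariate cell: maximum-likelihood logistic
regression of the 0/1 outcome on the covariate plus age in years
(continuous), both entered simultaneously. Fitting is Newton-type ML
(tolerance 1e-8, max 100 iterations) via statsmodels; an independent
brute-force likelihood-grid maximizer in the test suite verifies the
estimates to |Δβ| < 1e-3 on small fixtures. Results report β, SE, OR =
exp(β), Wald 95% CI exp(β ± 1.96·SE) and the Wald z-test p-value.

Degenerate inputs are handled explicitly: a constant outcome or constant
covariate is an error; a constant age column (collinear with the
intercept) is dropped and flagged; non-convergence or (quasi-)separation —
detected by optimizer failure or |β| > 15 — is returned as
`converged=False`, never silently. No multiple-testing adjustment is
applied across the 9-phenotype × covariate grid, matching the original
single-test reporting convention; a Bonferroni factor of 9 per covariate
is trivial to apply downstream if desired.

The fatal-variant analysis cross-tabulates carriers of fatal variants
(homozygous vs heterozygous carriage) against died-in-infancy vs survived
and applies the Pearson chi-square on 1 df. Yates continuity correction is
off by default (both versions are exposed; on the reference table both
give p < 0.001). Zero-margin tables raise an error recommending an exact
test. Patients carrying two *different* fatal variants in trans — possible
in synthetic data — are counted as heterozygous carriers, since they do
not satisfy the homozygous condition.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with defaults equal to the published study conditions: 162 patients,
homozygote fraction 89/162, allele region mix 126:12:14:23:107:42 over
DomainR-1..5 + non-domain, mutation-type mix 99:93:85:33:7:6:1, phenotype
intercepts at the logits of the published complete-case prevalences, and
per-phenotype NA rates equal to the published missingness. Ratios of
counts are used rather than the rounded printed percentages so the weight
vectors sum to exactly 1.

Each allele draws a region, then a codon uniformly within the region's
span, then a type; an HGVS string realizing that type is synthesized at
one of the codon's three bases (splice variants get a random ±1..20
intronic offset). Ages are uniform on 0–18 years — a synthetic convention
for a pediatric-skewed cohort with no published age distribution.
Phenotypes are Bernoulli through the logistic link on the patient's coded
covariates; NA masking is applied afterwards, missing-completely-at-random,
matching the complete-case assumption (configurable for sensitivity
studies). Optional fatal-variant rules make named variants lethal in
homozygotes with a given probability. A single `numpy.random.default_rng`
stream makes a config + seed fully reproducible across platforms.

What the generator does **not** emulate: linkage between the two alleles
of compound heterozygotes beyond the homozygote fraction, recurrent
founder alleles (every draw is independent, so allele-frequency spectra
are flatter than real cohorts), informative missingness, and any
correlation among phenotypes beyond their shared genotype covariates.
Passing recovery tests therefore show that the estimator is calibrated
under the assumed model, not that real cohorts satisfy those assumptions.

## Monte-Carlo calibration (sizes used)

The test suite runs: parameter recovery with β_halfx = −0.5 at n = 500
over 200 replicates (mean estimate within ±0.1, 95% CI coverage ≥ 90%);
type-I error of the Wald test under a null effect at n = 300 over 200
replicates (within [0.02, 0.09] at α = 0.05); region-frequency emulation
at n = 10,000 (within ±2 percentage points); and direction consistency —
with 5′-half risk elevated for failure to thrive, the fitted `halfx` OR
falls below 1 in ≥95% of 60 replicates at n = 500. Recovery configurations
set missingness to zero so that n refers to model rows.

## Known limitations

* The per-patient association model ignores within-patient allele
  dependence; it treats the coded product as a single patient-level
  exposure, exactly as the original analysis did.
* Published ORs from the real 162-patient cohort cannot be reproduced
  without the individual-level supplementary table; the package instead
  validates direction and calibration on synthetic cohorts.
* HGVS support covers the c.-notation subset seen in NS case reports
  (positions, intronic offsets, ranges, del/dup/ins/delins/substitution);
  no genomic or protein coordinate lifting, no reference-sequence
  validation, no pathogenicity prediction.
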