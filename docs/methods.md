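# Methods

## Variant normalisation

Multi-allelic records are split into one bi-allelic record per ALT
allele, and each (ref, alt) pair is reduced to parsimonious form by
trimming the shared suffix first, then the shared prefix, always
keeping at least one base per allele; the position advances by the
number of prefix bases removed. This is reference-free: it matches
`bcftools norm` for SNVs and for indels that are already left-aligned,
but it does not left-align indels through reference repeats, which
would require the genome FASTA. The synthetic cohorts and the intended
toy inputs are near-normalised, so full left-alignment is out of scope;
inputs with repeat-region indels should be passed through
`bcftools norm -f ref.fa` first.

Coordinates are 1-based throughout (VCF convention); region queries are
1-based inclusive.

## Genotype-level quality control

Filters are applied in a fixed order, each acting only on genotypes
still non-missing, which makes the chain idempotent:

1. **Depth/quality.** SNV genotypes with DP < 7, and indel (including
   MNV) genotypes with DP < 10, or genotypes with GQ < 20, are set
   missing. The conjunction is configurable (`dp_gq_logic`): the
   default OR treats either failure as disqualifying; AND (both must
   fail) is available for sensitivity analysis, since the convention is
   stated ambiguously in most pipeline descriptions. MNVs take the
   indel thresholds (the more conservative depth cutoff).
2. **Allele balance.** Heterozygous SNV genotypes that survived step 1
   are tested for a 50% expected alternate-read contribution with a
   two-sided exact binomial test on (ad_alt, ad_ref + ad_alt); at
   p₀ = ½ the two-sided test reduces to `min(1, 2·P(X ≤ min(k, n−k)))`.
   Genotypes with p ≤ 10⁻³ are set missing. Homozygous and indel
   genotypes are never touched by this rule.
3. **Missingness.** Per-variant missingness is recomputed and variants
   strictly above 50% are dropped (exactly 50% is retained).

A genotype whose DP, GQ or AD fields are absent fails the corresponding
rule — the conservative reading. Half-calls (`./1`) are treated as
missing on input. The QC report tallies, per variant, how many
genotypes each rule newly set missing and which variants were dropped.

## Annotation and masks

The package consumes a per-transcript annotation table (VEP-style, with
CADD and LOFTEE columns) rather than running an annotator; a 10-column
TSV dialect is the contract. Per variant and gene, one transcript is
selected: protein-coding transcripts are preferred when any exist, then
MANE select, then the canonical flag, with remaining ties broken on the
lexicographically smallest transcript id so the choice is independent
of row order. The most severe consequence term on the chosen transcript
is resolved against the standard Ensembl severity ranking, shipped as
an editable data file (`data/consequence_severity.txt`). Stop-gained,
frameshift, splice-acceptor and splice-donor consequences are
consolidated as protein-truncating variants (PTVs).

Three overlapping masks per gene: `hc_ptv` (PTV terms with LOFTEE HC),
`missense_cadd25` (missense with CADD phred ≥ 25, threshold inclusive),
and `damaging` (their union), each intersected with in-cohort
MAF < 0.1%. MAF is computed post-QC over non-missing genotypes and
folded to the minor allele; computing frequency in-cohort (rather than
against an external reference panel) matches a biobank-internal
workflow. Domain restriction keeps variants whose protein position
falls inside a wanted domain's 1-based inclusive residue range;
VEP-style `start-end` ranges use the start residue; variants with no
protein position are dropped. Domain coordinates are user data — the
shipped SF-1 spans (DBD 10–85, LBD 225–460) are illustrative synthetic
fixture values, not curated UniProt boundaries.

## Burden collapsing

CARRIER mode codes a sample 1 iff it has ≥ 1 non-missing genotype with
dosage ≥ 1 at any mask variant — the "dummy genotype" convention in
which every carrier is represented as a heterozygote regardless of how
many qualifying alleles it carries. ADDITIVE mode sums dosages over the
mask, so homozygotes contribute 2 and carriers in two domains count
once per allele. Missing genotypes contribute zero alleles rather than
excluding the sample; sample exclusion happens only on the phenotype
side (listwise deletion of missing trait/covariate values).

## Association model

The burden coefficient is estimated with a fixed-effects GLM:
identity-link Gaussian for quantitative traits, logit-link binomial for
binary traits, with covariates age, age², sex (dropped in single-sex
strata, where it is constant), the first 10 principal components, and
the sequencing batch one-hot encoded against its first level. A linear
mixed model (as used for exome-wide scans on related samples) is
deliberately not implemented: synthetic cohorts are generated
unrelated, so the random effect would be structurally zero; this is the
one intentional methodological substitution, and it matches the GLM the
motivating analysis itself used for domain-level tests.

Reported per fit: β (trait units, or log-odds), Wald SE, 95% CI as
β ± 1.96·SE (the CI method is a package choice), two-sided Wald p, and
for binary traits exp-transformed OR and CI. Zero carriers after
alignment and perfect separation raise errors rather than returning
spuriously precise numbers.

**Firth option.** With ~10⁻² carrier fractions the plain ML logistic
estimate of β carries a finite-sample bias of order 1/(carrier count):
measured at −0.0064 ± 0.0015 on the log-OR scale over 12 000 replicates
of the recovery protocol below, against +0.0008 ± 0.0015 for Firth's
bias-reduced penalised likelihood. `burden_glm(..., firth=True)`
therefore implements Firth's modified score
`X'(y − p + h(½ − p)) = 0` (h = weighted hat-matrix diagonal) via
damped Newton iteration, the standard remedy for rare-event logistic
burden tests; it also yields finite estimates under separation. Plain
ML remains the default, both for fidelity to the original analysis and
because the covariate-free closed-form identities (two-group mean
difference; 2×2-table log-OR) hold only for the unpenalised fit. The
recovery simulations use Firth for binary traits, since a mean-recovery
check presumes a centred estimator.

## Synthetic cohorts

The generator emulates the structure of a biobank exome cohort for one
gene: a panel of rare variants (dosage ~ Binomial(2, af) per sample, or
explicitly pinned carriers where exact counts matter), clean FORMAT
fields that pass every filter (DP ∈ [15, 35), GQ ∈ [30, 100),
read-balanced hets), covariates age ~ U(40, 70) years,
PC1–10 ~ N(0, 1), sex coded 1 = female, and a 3-level batch label with
frequencies proportional to the 50k/200k/450k release increments.
Quantitative traits are Gaussian around a linear predictor with modest
nonzero covariate effects (defaults: age 0.03/yr, age² −3·10⁻⁴,
PCs ±0.05, batch offsets up to 0.15, residual SD 5 — chosen as
plausible biobank-scale magnitudes); binary traits are Bernoulli under
a logistic model anchored at a 23% baseline prevalence, with the
covariate contribution centred so the baseline holds for non-carriers.
Trait effects multiply the additive allele count (or carrier indicator)
of the *true pre-QC* dosages, so ground truth is independent of
injected noise.

QC violations are injected at configured per-cell rates — low DP, low
GQ, skewed allelic reads at passing-depth hets (AD = (0, DP), giving
p ≤ 2·0.5¹⁵ for clean depths), and variant-level missingness (> 50% of
calls set `./.`) — pairwise disjoint by construction and logged in a
registry, so the QC report can be checked against the generator's
bookkeeping *exactly*, not statistically.

What the generator does not emulate: linkage disequilibrium,
relatedness, ancestry structure, genotype–covariate confounding (a
confound-free null is deliberate — it matches the GLM's assumptions),
sequencing batch effects on genotype quality, and X-chromosome
hemizygosity (all samples diploid; the SF-1 gene is autosomal). Passing
tests therefore certify the pipeline's correctness under its own model,
not robustness to population structure or cryptic relatedness.

Named fixtures: `sf1_mirror` (carriers pinned to reproduce the
motivating study's Ns exactly: 27 DBD / 80 LBD / 107 combined among
women with menopause data, 344 = 176 + 168 obesity-strata carriers, 3
hinge carriers excluded from domain masks; true effects −2.36
years/allele on menopause age and a female-specific obesity log-odds of
logit(0.323) − logit(0.23), calibrated to the published carrier
prevalence); `null_cohort` (all effects zero); `qc_torture` (high
violation rates, every rule exercised); `tiny_toy` (8 samples × 4
variants, hand-traceable). Tiny cohorts cannot satisfy an in-cohort
MAF < 0.1% filter — one het in 8 samples is already MAF 6% — so mask
construction on them takes an explicit `maf_threshold`.

## Validation experiments and problem sizes

- **Allele-balance oracle:** the scipy-based filter is checked against
  exhaustive enumeration over exact integer binomial coefficients for
  every read split with n ≤ 25, at 10⁻¹².
- **Closed-form GLM identities:** covariate-free quantitative fits equal
  the two-group mean difference, covariate-free binary fits the
  2×2-table log-odds ratio, at 10⁻⁸.
- **Type-I error:** 1000 zero-effect cohorts of 5000 samples; the
  rejection rate at α = 0.05 must lie in the exact binomial 99%
  interval.
- **Parameter recovery:** 200 replicate cohorts of 20 000 women (400
  cohorts, both sexes, for the odds ratio) at 1% carrier fraction, with
  the generator's truth set to each published estimate; the mean
  estimate must fall within 2 Monte-Carlo SEs of the truth. These sizes
  keep each experiment to a few minutes on one CPU while leaving
  Monte-Carlo SEs (~0.02 years; ~0.009 log-odds) far below the effects
  being recovered.

## Known limitations

- No reference-FASTA left-alignment of indels (see above).
- Linear mixed models, SKAT-type variance-component tests, and weighted
  burden kernels are out of scope; so is multiple-testing correction
  across traits (a Bonferroni helper exists but is not applied).
- Binary effects are conditional (covariate-adjusted) log-odds; they
  are comparable to marginal or linear-scale odds ratios only through
  recovery simulation, not algebraically.
- The annotation consumer trusts its input table; it does not re-derive
  consequences from sequence.
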