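# Methods

This note records the models, estimators, defaults and numerical conventions
behind `ibdarch`, and what the synthetic-data studies do and do not
demonstrate about real data.

## Cohort and genotype model

Samples carry a diagnosis (CD, UC, HC), an onset stratum (pediatric =
diagnosed before 17 years; adult; controls `not_applicable`), sex and age at
onset. The default cohort layouts follow the two-stage design the package
emulates: a screening cohort of 594 CD (356 pediatric) + 571 UC (311
pediatric) + 724 HC, and an enlarged validation cohort of 761 CD (424) +
734 UC (390) + 934 HC. The exome arm uses 21 + 22 VEO children (< 6 years at
diagnosis), 23 + 22 adult-onset (> 40 years) patients and 18 controls.

Genotypes are minor-allele dosages drawn per haplotype. Controls are sampled
under Hardy–Weinberg equilibrium at the panel MAF. Within-block linkage
disequilibrium uses a haplotype-copying scheme: each site's latent uniform
is, with probability `ld_rho`, copied from the previous site in the block,
and the allele is 1 iff the uniform falls below the site's allele frequency.
This preserves every marginal frequency exactly, induces monotone positive
LD in `ld_rho` (0 = independence, 1 = a single latent per block), and is the
simplest mechanism that makes distance-based block selection meaningful. No
attempt is made to match an empirical r² decay curve.

Case genotypes follow the multiplicative allelic risk model: a planted
allelic odds ratio OR at a site tilts the case haplotype frequency to
`p' = OR·p / (1 − p + OR·p)`, i.e. `odds(p') = OR·odds(p)`. Sampling
haplotypes directly at `p'` is distribution-identical to rejection sampling
individuals against per-allele relative risks under HWE, and needs no
rejection loop; this is the package's chosen implementation of that model.
Risk-allele identity defaults to the minor allele; a major-allele effect is
the same tilt with OR inverted.

## Pooling and array intensities

Pools are stratum-homogeneous (diagnosis × onset). The default policy
reproduces the emulated design: 9 / 16 / 10 / 14 pools for adult-UC /
pediatric-UC / adult-CD / pediatric-CD plus 30 control pools (49 + 30).
Samples are shuffled (seeded) within a stratum before chunking, mimicking
equimolar pool assembly. Two remainder policies exist for size-based
policies: `absorb` (default; the last full pool takes the remainder) and
`trailing` (a final smaller pool). Sex is recorded in metadata but not part
of the default stratum key, because the emulated pool counts are stated per
diagnosis × onset; a sex-stratified policy can be passed explicitly.

Array intensities use a standard pooled-array error decomposition: the true
pooled minor-allele fraction f receives additive Gaussian noise on the
fraction scale (default sd 0.02, clipped to [0, 1] rather than re-sampled —
at the MAFs used, clipping is a < 10⁻⁴ perturbation), and a multiplicative
heterozygote/channel bias k (default 1.0) applied to the B channel. The
estimator `A / (A + k·B)` with the matching k removes the bias exactly; the
per-pool frequency estimator is therefore unbiased up to noise, which the
Monte-Carlo estimator test confirms. The original study's intensity error
model was not published at this level of detail; these defaults are the
package's own standing choice, not a fit.

## Pooled screen statistic

Each SNP is tested per comparison with a pool-size-weighted Welch test on
pool-level frequency estimates: weighted means with ratio-estimator
variances (small-sample g/(g−1) correction; reduces to the textbook Welch
test at equal weights) and a Satterthwaite df. A t reference rather than a
normal one is used deliberately: arms have only 9–49 pools, and the t
reference is what keeps the empirical type-I error at 0.047 (2,000 null
sites, binomial SE 0.005) in the calibration study. Pools are the sampling
unit; failed pools (missing intensity) are dropped, never imputed, and a
site needs ≥ 2 usable pools per arm or it is skipped with a log entry.
P-values are two-sided; the sign of the weighted frequency difference is
stored separately for direction-concordance checks. Identical weighted
means return exactly (statistic 0, P 1); a nonzero difference with zero
estimated variance returns the smallest positive float so P stays in (0, 1].

Under the simulated global null the screen P-values are uniform
(Kolmogorov–Smirnov property test); with LD (`ld_rho` > 0) neighbouring
sites are correlated and only the marginal distribution, not the joint, is
calibrated — which is all the selection rules rely on.

## Selection rules

* Genome-wide: minimum P across the nine comparisons strictly below 5×10⁻⁸.
* LD blocks, per comparison: maximal runs of sites with P < 0.005 (strict)
  in which every adjacent qualifying pair is < 30 kb apart (strict; an exact
  30 kb gap splits); runs shorter than 10 are discarded; a run is emitted iff
  its best P is ≤ 10⁻⁴ (inclusive — the index SNP must be "at least" that
  significant), and the index SNP is the minimum-P member with ties broken
  by smallest genomic position. Contiguity is purely positional: no r² is
  computed, and non-qualifying sites between qualifying ones do not break a
  run. The scan is verified against an O(n²) brute-force enumeration on
  random panels, and is monotone as expected (lowering the member threshold
  never grows the selected set; widening the gap never shrinks it).
* Curated: configured site IDs pass through with provenance `curated`;
  unknown IDs are logged, not fatal.

MAF classes follow the study's usage: rare < 0.5 %, low-frequency 0.5–5 %
(both boundaries inclusive to low-frequency), common > 5 %. Rare and
low-frequency selections are flagged `suspect`: cohorts of this size cannot
produce genuine genome-wide signals at those frequencies, so such hits are
treated as probable false positives rather than silently dropped.

## Validation statistics

The allelic test builds the 2×2 allele table (het contributes one minor
allele, minor homozygote two; missing calls dropped), computes OR = ad/bc
with the Haldane–Anscombe +0.5 applied iff any cell is zero, a Woolf
(log-OR) 95 % CI on the corrected table, and a two-sided Fisher exact P on
the uncorrected integer table (robust to the small cells rare variants
produce; alleles treated as independent — the standard convention behind
single allelic ORs, valid under HWE within arms and documented here as an
assumption). A table monomorphic in both arms has OR = NaN and P = 1.
scipy's `fisher_exact` provides the P-value; an independent exhaustive
hypergeometric enumeration (exact log-binomial sums) serves as the test
oracle, with agreement to ~10⁻¹³ over all tables with total ≤ 80, compared
on canonical representatives of the row/column/transpose symmetry group
(the invariance itself is asserted separately).

Multiple testing uses Bonferroni. The default m is the number of SNP ×
comparison tests actually run; correcting over SNPs only is a config option.
m is always recorded in the run report, since the effective test count is a
reporting decision, not a mathematical one. The `nominal` flag requires both
P < 0.05 and an OR outside [0.83, 1.2]; the `corrected` flag requires only
P < 0.05/m, so the two flags are deliberately not nested.

Effect sizes: small 1.2 < OR < 1.5 or 0.63 < OR < 0.83; moderate
1.5 < OR < 2.0 or 0.5 < OR < 0.63; strong OR > 2.0 or OR < 0.5; boundary
values fall to the weaker class; [0.83, 1.2] is "none". The protective
edges are not reciprocals of the risk edges, so the two sides are binned
explicitly rather than by magnitude folding.

The sharing typology grades the six {IBD, CD, UC} × {pediatric, adult}
cells per SNP as corrected / nominal / none and derives: `shared` (same
phenotype corrected-significant in both age strata), `pediatric_unique` /
`adult_unique` (corrected significance confined to one stratum), `partial`
(both strata significant, disjoint phenotypes), `none`. The ambiguous
asterisk notation sometimes used for such tables is replaced by this
explicit pattern matrix.

## Exome burden

Rare = coding consequence (synonymous retained at the filtering stage) and
(novel, or every reference panel with data — 1000 Genomes, ESP, ExAC —
below 2 %, strict). The conjunctive all-panels rule is the default reading
of a three-panel criterion; `panel_rule="any"` is available. Variants with
neither panel data nor a novel flag are treated as novel and logged.
Deleterious = frameshift / stop-gained / splice always, missense iff
CADD-PHRED strictly above 10; synonymous and other classes never; missense
without a score is non-deleterious, logged. The full deleteriousness
criteria of the emulated study were more elaborate; this rule is the
documented stand-in behind a single classifier function.

The burden unit is the allele (het 1, hom 2, missing 0), matching a test of
allele frequencies; a carrier-count mode exists. For an "A/B" contrast the
2×2 is [deleterious, non-deleterious] × [B, A] and OR > 1 means deleterious
rare alleles are over-represented in B. The nine contrasts are emitted in
fixed reporting order for each gene set. The recurrent-homozygote screen
keeps deleterious rare variants homozygous in ≥ 2 VEO children and
homozygous in zero adults and zero controls; heterozygous carriage elsewhere
does not exclude, per the "as homozygotes" rule.

The exome simulator draws Poisson(8) rare sites per gene over two 150-gene
sets (deleterious fraction 0.45 under the null, novel fraction 0.3, carrier
allele frequencies uniform on [0.002, 0.02]); these defaults were chosen
once so that per-cell allele counts land in the few-hundreds, the regime of
the emulated burden tables (CI widths ≈ 1.04–1.45 around OR ≈ 1.2), and are
not tuned thereafter. Enrichment is planted by multiplying
deleterious-variant carrier frequencies in a (gene-set, group) cell by the
planted OR; for rare alleles the expected count odds ratio equals that
multiplier, which the recovery study confirms (mean log-OR error ≈ 0.003
at the study group sizes over 500 replicates).

## Determinism and orchestration

Every stage seed is spawned from the single config seed via
`numpy.random.SeedSequence`; strata are iterated in sorted order so draws
are order-stable; identical config + seed reproduces byte-identical
artifacts (verified by hashing all outputs of two runs). The config hash
(SHA-256 over the scientific parameters, output path excluded) is stamped
into every TSV header and the run report. Outputs carry no timestamps.

## Problem sizes in the checks

The calibration and recovery studies run at: 2,000 independent null sites
for pooled-test type-I error; 500 simulated cohorts (× 9 contrasts) for
burden type-I error; 200 replicates per planted allelic OR at 750 / 934
arms; 500 replicates for burden-OR recovery; 200 random panels of ≤ 500
sites for the block-scan equivalence; all 2×2 tables with total ≤ 80
(~1.93 M, via ~253 k canonical representatives) for the Fisher oracle.
These sizes make the binomial/Monte-Carlo tolerances used in the tests
(± 0.02 on a 0.05 rate; ± 0.1–0.15 on a mean log-OR) several standard
errors wide.

## Limitations

The generator does not simulate population structure, genotyping batch
effects, array probe density variation, pool-construction errors
(mis-assignment, unequal molarity), sequencing depth or call-rate
variation, or realistic site-frequency spectra; panel MAFs are uniform
below the rare threshold rather than SFS-shaped. Passing calibration here
therefore shows the statistics are implemented correctly and behave as
designed under their own assumptions — not that those assumptions hold in
any particular real cohort. Covariate-adjusted regression,
genomic-control inflation correction, haplotype phasing/r² estimation and
variant annotation are out of scope by design; annotations (gene,
consequence, CADD) arrive as inputs.
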