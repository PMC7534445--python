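# Methods

## The problem and the modeling stance

Cultivated blackberry and similar clonal crops are high-ploidy (4x–12x)
interspecific hybrids. Read-backed genotype calls give, per sample and
locus, a multiset of allele copies of the sample's ploidy — but dosage
calls are unreliable at moderate depth, so the unit of analysis here is
the **dominant marker**: does sample *s* carry allele *a* at least once.
Every statistic in the package is built on that binary encoding; dosage is
deliberately discarded everywhere downstream of the genotype table.

## Genotype tables and missingness

A multi-sample VCF is decoded into a locus-named table
(`"chrom:pos"`, 1-based, multiallelic records kept whole). A genotype with
any uncalled entry is treated as wholly missing — no partial-dosage
imputation rule is defensible without a dosage model. A separate
read-depth table enforces the rule that a zero-depth cell is missing even
if the caller emitted a genotype; depth is taken at the variant position.
The operation is idempotent and leaves covered calls untouched.

Locus filters: missing fraction strictly < 0.20 (a locus at exactly 20%
is removed), and 2–4 *observed* distinct alleles, counting REF when it
appears in a call. Both bounds are configurable.

## Screening and structure correction

Per column, Welch's unequal-variance t-test compares SSC (°Brix) between
carriers and non-carriers, with Welch–Satterthwaite degrees of freedom.
Columns with fewer than `min_class_size = 3` samples in either class, or
zero variance in both classes, are not tested and do not enter the
multiple-testing family (below 2 per class the df are undefined; 3 guards
zero-variance artifacts). Benjamini–Hochberg step-up q-values are computed
per run (per input VCF when two references are analyzed separately), via
`statsmodels.stats.multitest`; a brute-force step-up implementation serves
as the test oracle.

Structure correction fits two nested OLS models to each screen survivor:

* model 1 — `SSC ~ Group + Allele + Group×Allele`; the interaction is
  tested by the extra-sum-of-squares F against `Group + Allele`.
* model 2 — `SSC ~ Group + Allele-within-Group` (one allele coefficient
  per group); the joint F is against `Group`. With one group this reduces
  exactly to the pooled-variance two-sample F (identity tested to 1e-9).

Designs are built explicitly and degrees of freedom are taken from matrix
rank, so empty cells (a group carrying a single allele class) shrink the
numerator df instead of crashing, and a perfectly group-confounded allele
returns an `inestimable` flag. Fits use `numpy.linalg.lstsq` (the
genome-wide loop needs thousands of tiny fits); equality with
`statsmodels` OLS + `compare_f_test` is asserted in the test suite.

Selection rule: q ≤ α AND (interaction p > α, or interaction undefined
because only one group exists) AND within-group p ≤ α. A missing
within-group statistic never selects.

Tests never impute: samples with a missing entry are dropped column-wise.
Mean imputation is used only inside the PCA for structure inference.

## Structure inference (DAPC-style)

Columns with < 20% missing entries are kept, mean-imputed, centered, and
reduced by PCA to the fewest components reaching 90% of variance.
k-means (50 restarts, seeded) runs on the retained scores for each k in
1..10 and k minimizes

    BIC(k) = n·ln(WSS_k / n) + k·ln(n)

with ties going to the smallest k and a degenerate (zero-variance) matrix
short-circuiting to k = 1. The retention fraction, k range and restart
count are declared defaults, not estimates of any particular study's
choices; externally determined group labels can be supplied to bypass
inference entirely.

## Validation, concordance, and assay templates

Validation re-tests each marker within each location-year environment
(replicate measurements averaged per sample-environment); the BH family is
the set of markers within one environment — environments are separate
qualification questions, so no cross-environment correction is applied.

Genotype concordance between two methods compares unordered allele
multisets per position ("A:T" ≡ "T:A"). When per-position target alleles
are supplied, every allele is first collapsed to target/other: a biallelic
competitive-PCR assay cannot distinguish an off-assay allele from the
non-target allele, so sequencing "A:G" and assay "A:A" agree for a
T-target assay while "A:T" vs "T:T" do not. This projected comparison is
what reproduces the packaged 13-sample panel's 11/13 concordance; the raw
multiset rule (the default when no targets are given) counts 8/13 because
it also penalizes off-assay third alleles the assay could never report.

Consensus templates for assay design substitute the target allele verbatim
(never ambiguity-coded), IUPAC-code every other length-preserving variant
in the ±flank window (default 50 bp, configurable — submitted flank
lengths are vendor-specific), and flag length-changing variants instead of
splicing them in, since templates must stay ungapped; an indel within
25 bp of the target is marked as the known failure mode in which the assay
amplifies only the target haplotype and reports spurious homozygotes.
Assay attrition and exon-coverage percentages are reported to one decimal,
rounded half-up.

## Syntenic QTL intersection and bait tiling

Intervals are 1-based inclusive. A syntenic block (one segment per genome)
is a conserved trait region when QTL intervals overlapping its segments —
same genome, same chromosome, ≥ 1 shared base, no minimum overlap
fraction — come from at least `min_species` (default 2) distinct genomes.
The packaged block/QTL tables encode the printed coordinates of the three
conserved sugar-QTL regions as both the block segments and the per-crop
QTL intervals, since no finer interval data are published. Bait tiling
removes exons < 50 nt, places `bait_length/tiling`-spaced baits (default
80-mers at 2X) with a terminal bait flush to the exon end, and flags
designable exons shorter than one bait.

## The simulator: what it emulates, and what it does not

`SimConfig` defaults define the study conditions: ~40 clonal samples in a
cycled 4x/6x/8x ploidy mix, 2 population groups, mostly biallelic loci
(85/10/5% for 2/3/4 alleles), per-group allele frequencies drawn from a
symmetric Dirichlet (concentration 0.5; 0.1–0.2 models well-separated
programs), missing-completely-at-random zero-depth cells at 5%, baseline
10 °Brix, and four location-year environments (two locations × two
seasons) with offsets of ±0.15–0.35 °Brix — the magnitude of year-to-year
mean shifts seen in breeding records — each with 3 replicate
measurements, mirroring standard juicing protocols. `residual_sd`
(default 1.5 °Brix) is the per-sample-per-environment noise; replicate
scatter is off by default so the sample-environment value follows the
generative formula exactly. Association consumes each sample's mean SSC
across environments, as breeding analyses do, so the effective noise on
the discovery phenotype is `residual_sd/√n_env`.

Planted effects are dominant: carrying ≥ 1 copy shifts the genetic value
by the stated °Brix. Planted loci get allele frequencies shared across
groups with the causal allele's frequency solving a ~50% carrier rate for
the cohort's mean ploidy (balanced classes, the informative case).
Structure-confounded effects are planted as *pure* group × allele
interactions — the effect applies with opposite sign per group to the
group-centered carrier indicator — contributing no group main effect and
no marginal effect; an earlier construction on the raw indicator leaks a
large spurious group mean difference (sum of effects × carrier rate),
which is an artifact, not a study condition.

Not emulated: linkage disequilibrium between loci, pedigree structure,
read-level errors, dosage-informative depth ratios, genotype-call error,
and non-random missingness. Passing tests therefore demonstrate the
statistical machinery under clean MCAR dominant-marker conditions, not
robustness to call errors or LD-induced dependence among columns.

## Numerical choices

Welch statistics are computed vectorized across all columns (masked sums;
per-column agreement with `scipy.stats.ttest_ind` is asserted to 1e-10);
tiny negative variances from cancellation are clipped at zero. BH
q-values come from statsmodels. F-tests use rank-aware df as above.
Percentages printed to one decimal use decimal half-up rounding, not
banker's rounding. The k-means BIC guards `WSS = 0` with a floor of
1e-12. All simulator draws come from one `numpy` Generator in a fixed
order (allele counts, frequencies, dosages by group/ploidy/allele-count
batch, missingness, depth, environment residuals, replicate noise), so a
seed fixes the cohort bitwise.

## Known limitations

* **Welch at dominant-marker class sizes.** With ~40 samples, many
  presence/absence columns have 3–8 samples in the minor class, where the
  Welch approximation is mildly liberal (empirical size ~0.055 at nominal
  0.05, approaching ~0.051 even at 20 vs 20; verified against scipy on
  normal draws). Aggregate error-rate estimates over many columns of one
  cohort are also strongly dependent, since every column shares the same
  phenotype vector: per-cohort rejection rates have SD ~0.07, so
  multi-cohort averages fluctuate far more than an independence-based
  binomial interval suggests.
* **Marginal screening under a dense polygenic background.** Each Welch
  column treats all other causal variation as noise. If many alleles with
  sizable effects segregate at once (e.g. 20 alleles of 0.5–2.0 °Brix at
  ~50% carrier rate ⇒ ~8.6 °Brix² of background variance, an implausibly
  high heritability for SSC), the effective test SD approaches 3 °Brix and
  BH-corrected recall collapses for effects under ~2 °Brix, while the
  conditioning of the within-group gate on screen survivors inflates the
  realized FDR. With one or a few segregating QTL — the regime the
  selection rule targets — within-group power for a 1.5 °Brix allele at
  n = 96 is ~0.95 (tested).
* Mixed-model (kinship) correction, dosage-aware tests, haplotype
  phasing, and permutation-based genome-wide thresholds are out of scope.
* The acceptance studies use 200 null cohorts (40 × 1000 loci),
  200–500 recovery replicates (96 × 1000 loci) and 100 structure-recovery
  cohorts (40 × 300 loci); these sizes give Monte-Carlo SEs well under the
  decision margins while keeping a full run in the low minutes on one
  core.
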