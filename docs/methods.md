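# Methods

This note documents the models and procedures implemented in `svqtl`,
the defaults that matter, what the synthetic cohorts do and do not
emulate, and the numerical choices made where the design was open.

## SV harmonization

An SV record is an insertion, deletion or inversion of at least 50 bp
with 0-based half-open coordinates under the anchor-before convention:
the printed VCF `(POS, END)` pair equals the internal span numerically,
`END − POS = |SVLEN|` for deletions, and `END = POS` for insertions.
IDs follow the `napu_<chrom>_<pos>_<end>_<TYPE>_<signedlen>` style; the
record carries explicit coordinates as well, since that ID convention
leaves the base offset ambiguous on its own.

### Collapse rule

Two records are mergeable when all of the following hold:

- same chromosome, breakpoint distance ≤ `refdist` (default 500 bp, the
  default of the established SV-merging tool);
- size similarity `min(|l_a|,|l_b|)/max(|l_a|,|l_b|)` ≥ 0.75;
- for two sequence-resolved insertions, sequence similarity
  `1 − editdistance/max(len)` ≥ 0.75. Deletions and inversions merge on
  span and size only — their content is reference-determined — and
  inversions use reciprocal span overlap in place of the size ratio;
- same type, unless the pass is type-blind.

Clustering is greedy and seed-based: seeds are taken in order of quality
descending, then start ascending, then |length| descending (record name
as the final deterministic tie-break); an unassigned record joins the
cluster if it matches the *seed* (no transitive chaining); the cluster
is emitted with the seed's coordinates, sequence and quality, genotypes
merged across members (the seed wins conflicts, which are logged), and
provenance the union of member provenance. The output is invariant to
input order, idempotent, and on small instances provably identical to an
exhaustive all-pairs oracle that applies the same seed ordering (checked
for 200 random instances in the test suite).

Assembly-based callers cannot assign quality scores, so assembly calls
are forced to quality 0 before cross-caller collapse; wherever both
callers describe one variant the read-based representation therefore
survives as the seed. Symbolic deletion alleles are resolved from the
reference before cross-caller comparison.

The multi-allelic cleanup pass re-collapses records within 1 kb with
size similarity ≥ 0.5, ignoring type and sequence — so an insertion and
a deletion representing the same event at one locus combine. These loose
thresholds are a documented package choice (the upstream description
says only that multi-allelic variants were "merged more loosely").
Cross-cohort merging uses the strict thresholds with variants above
60 kb exempted from merging, and requires disjoint sample names.

Coverage-based reference genotyping converts a missing genotype to 0/0
only when the variant is assembly-supported and **both** haplotype
coverage beds fully contain the variant span (a single-haplotype rule
would mis-call hemizygous misses); called genotypes are never altered.

## Genotype QC

Per-variant statistics are computed over validly genotyped samples only:
allele frequency `(n_Aa + 2 n_aa)/(2 n_called)`, carrier frequency
`(n_Aa + n_aa)/n_called` (explicit 0/0 calls count in the denominator),
call rate over all samples. The Hardy–Weinberg test is the exact
conditional test: with allele counts fixed, P(het = h) ∝
`n!/(n_AA! n_Aa! n_aa!) · 2^h`, and the p-value sums all configurations
no more probable than the observed one. The exact test is used because
SV genotype classes are often tiny; it is verified against a full
enumeration oracle for every table with ≤ 20 alleles.

Filters remove variants with MAF < 0.05, call rate < 0.95, HWE
p < 0.001, or a non-autosomal chromosome. The source protocol's filter
list reads "HWE p-value > 0.001" under the removals, which contradicts
universal practice and is implemented in the conventional direction;
`hwe_remove_low=False` restores the literal reading.

LD: r² is the squared Pearson correlation of dosages over jointly
called samples; D′ uses EM-estimated haplotype frequencies (only the
double heterozygote is ambiguous) normalized by the frequency-bound
maximum |D|. PCA standardizes features (missing values mean-imputed),
and the retained component count is the discrete knee of the
explained-variance curve — the index maximizing the vertical distance
from the chord of the normalized curve — with a fall-back to k = 1 and
a warning when the curve has no interior knee.

## Methylation phenotypes and age models

Adaptive windows tile each chromosome without gaps: a window starts at
the previous window's end (the first at the first CpG), spans at least
1 kb and extends until it holds at least 50 CpGs; trailing CpGs that
cannot fill a window are dropped. Promoters are a 60 bp database core
padded 1 kb each side (an alternative description pads 2 kb; the 1 kb
reading is implemented and the pad is a parameter). Gene bodies use the
isoform with the most exons (ties: longest span, then lowest start).

Aggregation is the unweighted mean methylated fraction over CpGs with
coverage ≥ 5 reads, requiring ≥ 10 qualifying CpGs per region per
sample; regions missing in more than 25% of samples are dropped. A
coverage-weighted mean was deliberately not used: the phenotype is the
plain average the windowing describes.

Age models are OLS of region methylation on age with PMI and sex
covariates; the reported R² is the age partial R² `t²/(t² + df)`; q is
Benjamini–Hochberg within region kind. The "large effect" screen keeps
regions with |slope × age span| > 0.1 and R² > 0.4 — the threshold is
applied to the total change across the observed age span because a
0.1/year slope is impossible for fractions sustained over decades; the
interpretation is exposed as parameters. Cross-cohort concordance
requires q < 0.05 in both cohorts with the same slope sign.

## Cis-QTL mapping

Phenotypes with more than 25% missingness are dropped; the rest are
rank-inverse-normal transformed (ties averaged, ranks mapped through
Φ⁻¹(r/(n+1))) and affinely rescaled to [0,1]. Both steps are monotone,
so effect signs are scale-free. The cis window is ±1 Mb around the
anchor — the TSS for genes, the region start for methylation regions
(with a 2 Mb window the anchor choice within the region is nearly
immaterial) — inclusive at the boundary.

For each pair, phenotype and mean-imputed dosage are residualized on
the covariates (intercept included; rank-deficient covariate matrices
are rejected naming the collinear columns) and the slope, SE and t come
from the simple regression of residuals with n − p_covariates − 2
degrees of freedom.

Per-phenotype multiple testing uses the permutation scheme of the
established cis-QTL engines: B permutations (default 1,000) of the
residualized phenotype, each recording the maximum |correlation| over
cis variants (monotone in max |t| at fixed df); the raw empirical p is
the add-one estimator `(1 + #{perm ≥ obs})/(B + 1)`. Because the add-one
floor 1/(B+1) is too coarse for genome-wide q-values, a Beta
distribution is fitted by maximum likelihood to the permutation null of
the lead nominal p and the smoothed empirical p is its CDF at the
observed lead; both values are reported and the smoothed one feeds the
q-values. Every phenotype draws its permutations from a named substream
of the top-level seed, so results do not depend on scan order.

Study-wide significance is Storey's q < 0.05 with π₀ estimated by the
cubic-spline smoother over λ ∈ {0.05, …, 0.95} (fall-back π₀ = 1 when
the estimate leaves (0, 1]; BH with a warning below 10 phenotypes).

## Fine-mapping

Candidates are the top 100 variants by ascending nominal p (ties:
|β| descending, then id), appending the best SV when none made the top
100 and the locus has one. The LD matrix is the Pearson correlation of
mean-imputed dosages with a ridge ε = 10⁻⁶ on the diagonal (duplicate
or perfect-LD candidates otherwise make it singular; posteriors move by
< 10⁻⁶ across ε ∈ [10⁻⁸, 10⁻⁴] for well-conditioned matrices).

Under the single-causal summary-statistic model, z ~ N(0, Σ) with no
causal and z ~ N(0, Σ + s²·Σ_iΣ_iᵀ) when variant i is causal. The prior
over the m single-causal configurations is uniform and the no-causal
configuration is excluded, since loci arrive pre-selected as
significant — a documented choice that differs from including a null
model. The non-centrality scale defaults to s = 5.2, the conventional
default of the reference fine-mapping implementation. Likelihoods are
evaluated by Cholesky factorization in log space; with Σ = I the
posterior reduces to ρ_i ∝ exp(z_i² s²/(2(1+s²))), the closed form the
tests pin.

## Enrichment and concordance

The SV-vs-small-variant 2×2 odds ratio uses the Woolf (log-normal) 95%
CI, with the Haldane–Anscombe +0.5 correction applied only when a zero
cell exists. "QTL" status means appearing as a significant lead in the
joint run; the denominator is the set of tested (post-QC) variants —
the exact denominator is a configuration choice since more than one is
defensible. Carrier-frequency concordance is the Pearson r over shared
variants meeting a minimum-genotyped threshold, with a permutation p
available for the positive-association claim.

## The synthetic cohorts

The generator's defaults are the study conditions: a 205-sample cohort
(ages 15–96, three collection-site labels) and a 154-sample companion
(ages 18–85); an SV type mix of 56% insertions / 43.9% deletions /
0.12% inversions with insertion lengths bimodal around 300 bp and 6 kb
(the Alu and LINE1 modes) and sizes clipped to [50 bp, 60 kb]; a
rare-heavy allele-frequency law (70% Beta(0.15, 1.5), 30% Beta(2, 4))
under which roughly half of variants have MAF below 1%, echoing the SV
frequency spectrum of real long-read call sets.

LD is a block-wise Gaussian copula: within a block (default 50 kb)
every haplotype's latent Gaussians share one factor with loading
√ρ (default ρ = 0.7), so thresholding at Φ⁻¹(AF) gives haplotypes with
within-block latent correlation ρ and exact marginal frequencies. This
was chosen over coalescent simulation because it is desk-scale and
directly controls the r² structure fine-mapping is tested against.
Genotypes are the sum of two haplotypes. A second cohort can reuse the
first's catalog — same variants and allele frequencies, fresh
haplotypes — which is what cross-cohort merge and concordance stages
consume.

Caller observation noise: each true SV carried by a sample is observed
per caller with probability 1 − dropout (default 0.1), its start
jittered N(0, 30 bp), insertion sequences mutated by per-base
substitutions at rate 0.05 (substitutions only; the resulting edit
distance ≈ rate × length is what the similarity threshold sees), and
read-caller deletions/inversions made symbolic with probability 0.3.
Assembly calls have quality 0, read calls uniform in [20, 60]. Coverage
beds tile the genome in 10 kb tiles, each uncovered independently at
the gap rate (default 0.05), so the expected uncovered fraction equals
the gap rate exactly.

Expression is linear in dosage with Gaussian noise
(y = β·g + covariate effects + ε); planted effects draw β ~ N(0, 0.6)
with |β| ≥ 0.2 against noise SD 1 — deliberately spanning detectable
and borderline effects. Methylation fractions are
`expit(baseline + slope·(age − mean) + β·g + noise)` per CpG, with
bimodal baselines (80% hypermethylated) reproducing the hyper/hypo
distribution of brain methylomes and the logit scale keeping fractions
in [0, 1]; region-level effects shift every CpG in the region. CpG
coordinates mix dense island-like clusters (~10 bp spacing) with a
sparse ~700 bp background, so adaptive windows span 1 kb to tens of kb.

What the generator does **not** emulate: read-level errors, reference
bias, recurrent mutation and suballele diversity of real SVs,
population structure and admixture, trans effects, haplotype-specific
methylation, and sex chromosomes. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated generative
model — not robustness to every failure mode of real long-read data;
in particular real SV merging must contend with recurrent
non-identical alleles that this generator does not produce.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run the stages at desk-scale
sizes chosen to estimate each property tightly: merge recovery on
2 × 50 × 2,000 noisy caller views; QTL null calibration on 20 (tests)
or 5 (script) replicates of 500/300 phenotypes × B = 1,000; power on
planted β = 1, MAF 0.3, σ = 0.5, n = 200 replicates; fine-mapping on
40–50 LD-block loci with the causal variant at 20% explained variance;
age-model error on 1,000 null regions. All randomness flows from one
integer seed through named substreams (`SeedSequence([seed,
crc32(name)])`), so every run — including the full CLI chain — is
byte-reproducible given the seed.

## Known limitations

- Breakends, duplications-as-a-type and nested SVs are out of scope;
  inversion merging never compares sequence.
- The merge engine's no-chaining rule can split a wide jitter cloud in
  rare cases; the recovery tests bound this below 5% under the stated
  noise.
- Storey's π₀ smoother is unstable below a few dozen phenotypes (hence
  the BH fall-back).
- The single-causal model cannot represent allelic series; loci with
  two true causal variants will concentrate posterior on one of them.
- `fit_age_models` loops per region when values contain missing
  entries; complete matrices are solved in one vectorized pass.
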