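# svqtl

Post-sequencing analysis chain for long-read population studies of the
human brain: harmonizing structural-variant (SV) calls across callers,
samples and cohorts; variant QC; aggregated DNA-methylation phenotyping;
cis-QTL mapping of expression and methylation; single-causal
fine-mapping; and SV-enrichment statistics. Everything runs end to end
on synthetic cohorts that emulate the structure of a two-cohort
long-read brain study (two SV callers per sample, assembly-coverage
beds, bulk expression, per-CpG methylation, age/sex/PMI covariates), so
the whole pipeline is testable without any restricted-access data.

It is written for methods developers and analysts who want a tested,
reusable reference implementation of this analysis chain — each stage is
an importable function operating on standard containers (pandas
DataFrames, a dosage `GenotypeMatrix`, dataclass `SVRecord`s) with
plain-text formats (VCF, BED, bedMethyl-like TSV) at the boundaries.

## The methods at the core

**SV harmonization** is a Truvari-style greedy collapse. Two records may
merge when their breakpoints are within `refdist` (500 bp), their size
ratio `min(|l_a|,|l_b|)/max(|l_a|,|l_b|) >= 0.75`, and — for
sequence-resolved insertions — their sequence similarity
`1 - editdistance/max(len) >= 0.75`. Cluster seeds are chosen by quality
descending (ties: start, then |length|), members are compared to the
seed only (no transitive chaining), and the seed's representation is
emitted. Assembly-based callers cannot score their calls, so their
quality is fixed at 0 and the read-based representation survives
cross-caller collapse. Residual multi-allelic loci are re-collapsed
loosely (1 kb, size ratio 0.5, type-blind), and missing genotypes become
0/0 where both assembly haplotypes cover the span. Cross-cohort merging
exempts variants above 60 kb.

**Cis-QTL mapping**: phenotypes are rank-inverse-normal transformed and
min-max scaled; every variant within ±1 Mb of the phenotype anchor (TSS
or region start) is tested by covariate-residualized regression
(β, SE, t, nominal p). Per phenotype, B permutations of the residualized
phenotype give the null of the lead statistic; the empirical p is
`(1 + #{perm max ≥ obs max})/(B+1)` with a Beta-distribution fit for
tail smoothing, and significance is Storey q < 0.05.

**Single-causal fine-mapping**: for the top 100 variants (plus the best
SV if none made the top 100), with z = β/SE and LD matrix Σ, the
posterior that variant *i* is causal is

    ρ_i ∝ N(z; 0, Σ + s²·Σ_i·Σ_iᵀ),   Σρ_i = 1

with non-centrality prior s = 5.2 and a uniform prior over single-causal
configurations. A locus is "SV-led" when the rank-1 candidate is an SV.

**Methylation phenotypes**: adaptive windows ≥ 1 kb extended to ≥ 50
CpGs; CGIs; promoters (60 bp core ± 1 kb); gene bodies (isoform with the
most exons). Region values are unweighted means over CpGs with ≥ 5
reads, requiring ≥ 10 qualifying CpGs. Age association is OLS on age
with PMI and sex covariates, BH-corrected within region kind.

Supporting statistics: exact conditional Hardy-Weinberg test; EM-based
D′ and dosage r²; PCA with the component count chosen at the knee
(maximum chord distance) of the explained-variance curve; Woolf CI odds
ratios with Haldane correction; carrier-frequency Pearson concordance.

## Worked example

`examples/` holds one short script per capability. For instance:

```bash
$ python examples/02_merge_svs.py
assembly: 797 raw calls -> 82 collapsed
read: 787 raw calls -> 82 collapsed
harmonized union: 83 SVs
coverage-assigned + called 0/0 genotypes: 1401
```

~800 per-sample calls per caller collapse to one record per polymorphic
planted SV, the two callers' views union to 83 representative records,
and coverage licenses reference genotypes where no call was made.

```bash
$ python examples/05_cis_qtl.py
5077 cis pairs over 60 genes (0 untestable)
significant eGenes (q<0.05): 10
planted eQTL recovered: 10/15
```

Ten genes reach q < 0.05; the recovered effects are the planted ones
whose causal variant survived the MAF/call-rate/HWE filters and whose
|β| is large enough to detect at n = 150 — the weakest planted effects
stay sub-threshold, as they would in a real cohort of this size.

```bash
$ python examples/06_finemap.py
causal variant rank: 1, posterior 1.000
```

The CLI mirrors the same stages (`svqtl simulate | merge | qc | methyl |
qtl | finemap | enrich`) for shell-driven runs; outputs are
deterministic given `--seed`.

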