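"""Harmonize two callers' SV calls into one union set.

Collapses per-sample calls within each caller, resolves symbolic
deletions, unions across callers keeping the higher-quality (read-based)
representation, and assigns 0/0 genotypes where assembly coverage
licenses them.
"""

from svqtl.merge import (
    MergeParams,
    cluster_and_collapse,
    collapse_multiallelic,
    genotype_from_coverage,
    harmonize_callers,
)
from svqtl.simulate import CohortSpec, generate_cohort

cohort = generate_cohort(
    CohortSpec(name="demo", n_samples=30, n_sv=120, n_snv=0,
               chrom_length=6_000_000),
    seed=11, n_genes=5, n_eqtl=0, n_mqtl=0, n_age_regions=0,
)
params = MergeParams()  # 75% size/sequence similarity, 500 bp refdist

per_caller = {}
for caller, by_sample in cohort.caller_calls.items():
    records = [r for recs in by_sample.values() for r in recs]
    per_caller[caller] = cluster_and_collapse(records, params)
    print(f"{caller}: {len(records)} raw calls -> "
          f"{len(per_caller[caller])} collapsed")

union = harmonize_callers(per_caller["assembly"], per_caller["read"],
                          cohort.reference, params)
union = genotype_from_coverage(union, cohort.coverage, cohort.gmat.samples)
union = collapse_multiallelic(union)
n_ref = sum(1 for r in union for g in r.genotypes.values() if g == 0)
print(f"harmonized union: {len(union)} SVs")
print(f"coverage-assigned + called 0/0 genotypes: {n_ref}")
# The union should sit near the number of polymorphic planted SVs: each
# variant seen by both callers collapses to one representative record.
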