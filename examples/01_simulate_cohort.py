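"""Generate a small synthetic brain cohort and inspect its structure.

Builds LD-structured genotypes for SVs and small variants, two noisy
caller views, coverage beds, expression and methylation with planted
effects, then prints the headline numbers of the bundle.
"""

from svqtl.simulate import CohortSpec, generate_cohort

spec = CohortSpec(name="demo", n_samples=40, n_sv=80, n_snv=240,
                  chrom_length=4_000_000)
cohort = generate_cohort(spec, seed=7, n_genes=30, n_eqtl=8)

n_calls = {c: sum(len(v) for v in d.values())
           for c, d in cohort.caller_calls.items()}
print(f"samples: {cohort.gmat.n_samples}")
print(f"variants: {cohort.gmat.n_variants} "
      f"({int(cohort.catalog['is_sv'].sum())} SVs)")
print(f"per-caller call records: {n_calls}")
print(f"planted cis effects: {len(cohort.truth.effects)}")
print(f"age-trend regions: {len(cohort.truth.age_slopes)}")
# Each caller observes every carrier with some dropout, so call records
# exceed the SV count; the truth table is what recovery is tested against.
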