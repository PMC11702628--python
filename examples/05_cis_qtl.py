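"""Cis-eQTL mapping on a cohort with planted effects.

Quantile-normalizes expression, enumerates variant-gene pairs within
+/- 1 Mb of each TSS, fits covariate-adjusted nominal associations,
calibrates per-gene lead p-values by permutation (with beta tail
smoothing) and declares significance at Storey q < 0.05.
"""

from svqtl.qc import apply_qc_filters
from svqtl.qtl import (
    declare_significant,
    enumerate_cis_pairs,
    fit_nominal,
    normalize_phenotypes,
    permutation_adjust,
)
from svqtl.simulate import CohortSpec, generate_cohort

cohort = generate_cohort(
    CohortSpec(name="demo", n_samples=150, n_sv=80, n_snv=320,
               chrom_length=6_000_000, common_fraction=0.6),
    seed=9, n_genes=60, n_eqtl=15,
    # plant clearly-powered effects for the demonstration
    eqtl_beta_sd=1.0, eqtl_beta_min=0.6,
)

filtered, _ = apply_qc_filters(cohort.gmat)
phen = normalize_phenotypes(cohort.expression)
pairs, untestable = enumerate_cis_pairs(
    cohort.expression_meta.loc[phen.index], filtered.variants
)
print(f"{len(pairs)} cis pairs over {len(phen)} genes "
      f"({len(untestable)} untestable)")

assoc = fit_nominal(pairs, phen, filtered, cohort.covariates)
leads = permutation_adjust(assoc, phen, filtered, cohort.covariates,
                           permutations=500, seed=9)
leads = declare_significant(leads)
print(f"significant eGenes (q<0.05): {int(leads['significant'].sum())}")

planted = {e.phenotype_id: e.variant_id for e in cohort.truth.effects
           if e.kind == "expression"}
testable = [p for p, v in planted.items()
            if p in leads.index and v in filtered.variants.index]
hits = int(leads.loc[testable, "significant"].sum())
print(f"planted eQTL recovered: {hits}/{len(testable)}")
# Recovery depends on the planted |beta| (drawn near 0.2-1.5 on the
# noise SD scale); the weakest planted effects stay sub-threshold, which
# is the behaviour a real cohort of this size shows.
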