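"""SV-vs-small-variant enrichment and cross-cohort frequency concordance.

Computes the odds ratio (with Woolf 95% CI) for an SV to be a QTL
compared to a small variant, and the Pearson concordance of carrier
frequencies between two cohorts segregating the same variants.
"""

import pandas as pd

from svqtl.enrichment import frequency_concordance, qtl_enrichment_or
from svqtl.records import MISSING
from svqtl.simulate import CohortSpec, hbcc_like, simulate_genotypes

# the worked 2x2: 10/90 SV-QTL/non vs 100/9900 small-QTL/non
res = qtl_enrichment_or(10, 90, 100, 9900)
print(f"OR={res.odds_ratio:.1f} (95% CI {res.ci_lower:.2f}-{res.ci_upper:.2f})")

spec_a = CohortSpec(name="A", n_samples=200, n_sv=100, n_snv=300,
                    chrom_length=5_000_000)
gmat_a, catalog = simulate_genotypes(spec_a, seed=13)
spec_b = hbcc_like("B")
spec_b.chrom_length = 5_000_000
gmat_b, _ = simulate_genotypes(spec_b, seed=13, catalog=catalog)


def carrier(gmat):
    freqs, ns = {}, {}
    for i, vid in enumerate(gmat.variants.index):
        d = gmat.dosages[i]
        called = d != MISSING
        if called.sum():
            freqs[vid] = float((d[called] >= 1).mean())
            ns[vid] = int(called.sum())
    return pd.Series(freqs), pd.Series(ns)


fa, na = carrier(gmat_a)
fb, nb = carrier(gmat_b)
conc = frequency_concordance(fa, fb, na, nb, min_genotyped=140)
print(f"carrier-frequency concordance: r={conc.pearson_r:.3f} "
      f"over {conc.n_variants} variants")
# Shared allele frequencies with independent sampling noise should give
# r near 1; the OR above reproduces the closed-form Woolf interval.
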