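"""Single-causal fine-mapping at a simulated locus.

Builds an LD-blocked locus, computes per-variant z-scores for a
phenotype driven by one causal variant, and ranks candidates by the
posterior causal probability under the causal-set-size-1 model.
"""

import numpy as np

from svqtl.finemap import FineMapParams, single_causal_posterior
from svqtl.simulate import CohortSpec, simulate_genotypes
from svqtl._seeds import substream

spec = CohortSpec(name="locus", n_samples=200, n_sv=0, n_snv=100,
                  chrom_length=1_000_000, ld_block_length=100_000,
                  within_block_correlation=0.7, common_fraction=1.0)
gmat, _ = simulate_genotypes(spec, seed=21)
rng = substream(21, "phenotype")

D = gmat.dosages.astype(float)
D = D[D.std(axis=1) > 0.3]
causal = int(rng.integers(D.shape[0]))
g = D[causal]
sigma = np.sqrt(g.var() * 4)  # causal variant explains 20% of variance
y = g + rng.standard_normal(200) * sigma

Dc = D - D.mean(axis=1, keepdims=True)
yc = y - y.mean()
gg = (Dc**2).sum(axis=1)
beta = Dc @ yc / gg
se = np.sqrt(((yc**2).sum() - beta**2 * gg) / (200 - 2) / gg)
z = beta / se

sigma_ld = np.corrcoef(D) + 1e-6 * np.eye(D.shape[0])
post = single_causal_posterior(z, sigma_ld, FineMapParams())
top = post.sort_values("rank").head(3)
print(f"causal variant index: {causal}")
print(top.assign(index=top.index)[["index", "rho", "rank"]].to_string(index=False))
print(f"causal variant rank: {int(post['rank'].iloc[causal])}, "
      f"posterior {post['rho'].iloc[causal]:.3f}")
# With ~10-variant LD blocks at r ~ 0.5-0.7 the causal variant should
# take rank 1 with most of the posterior mass concentrated on its block.
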