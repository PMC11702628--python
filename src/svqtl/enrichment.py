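"""Cross-cutting enrichment and concordance statistics.

The SV-vs-small-variant QTL enrichment is a 2x2 odds ratio with a Woolf
(log-scale normal) confidence interval; a Haldane-Anscombe 0.5 correction
is applied only when a zero cell exists. Carrier-frequency concordance
between cohorts or panels is a Pearson correlation over variants meeting
a minimum-genotyped-samples threshold, with carrier frequency defined as
the share of validly genotyped samples carrying at least one alternate
allele.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeds import substream


@dataclass
class EnrichmentResult:
    sv_qtl: int
    sv_non_qtl: int
    small_qtl: int
    small_non_qtl: int
    odds_ratio: float
    ci_lower: float
    ci_upper: float


def qtl_enrichment_or(
    sv_qtl: int, sv_non_qtl: int, small_qtl: int, small_non_qtl: int
) -> EnrichmentResult:
    """Odds ratio (with 95% Woolf CI) for an SV to be a QTL vs a small variant."""
    cells = (sv_qtl, sv_non_qtl, small_qtl, small_non_qtl)
    if any(c < 0 for c in cells):
        raise ValueError("cell counts must be non-negative")
    if sum(cells) == 0:
        raise ValueError("empty 2x2 table")
    a, b, c, d = (float(x) for x in cells)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se_log = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = float(np.exp(np.log(or_) - 1.96 * se_log))
    hi = float(np.exp(np.log(or_) + 1.96 * se_log))
    return EnrichmentResult(
        sv_qtl=sv_qtl,
        sv_non_qtl=sv_non_qtl,
        small_qtl=small_qtl,
        small_non_qtl=small_non_qtl,
        odds_ratio=float(or_),
        ci_lower=lo,
        ci_upper=hi,
    )


def enrichment_from_table(table: pd.DataFrame) -> EnrichmentResult:
    """Enrichment OR from a variant table with boolean is_sv / is_qtl columns."""
    a = int((table["is_sv"] & table["is_qtl"]).sum())
    b = int((table["is_sv"] & ~table["is_qtl"]).sum())
    c = int((~table["is_sv"] & table["is_qtl"]).sum())
    d = int((~table["is_sv"] & ~table["is_qtl"]).sum())
    return qtl_enrichment_or(a, b, c, d)


@dataclass
class ConcordanceResult:
    n_variants: int
    pearson_r: float
    pairs: pd.DataFrame  # per-variant (freq_a, freq_b) scatter pairs


def frequency_concordance(
    freq_a: pd.Series,
    freq_b: pd.Series,
    n_genotyped_a: pd.Series | None = None,
    n_genotyped_b: pd.Series | None = None,
    min_genotyped: int = 0,
) -> ConcordanceResult:
    """Pearson concordance of carrier frequencies over shared variants.

    Variants with fewer than ``min_genotyped`` validly genotyped samples
    in either set are excluded. Fewer than 3 shared variants, or a
    zero-variance frequency vector, is an error.
    """
    shared = freq_a.index.intersection(freq_b.index)
    if min_genotyped and n_genotyped_a is not None:
        ok = (n_genotyped_a.reindex(shared) >= min_genotyped) & (
            n_genotyped_b.reindex(shared) >= min_genotyped
        )
        shared = shared[ok.to_numpy(dtype=bool)]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared variants meet the threshold")
    x = freq_a.loc[shared].to_numpy(dtype=float)
    y = freq_b.loc[shared].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance frequencies: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    pairs = pd.DataFrame({"freq_a": x, "freq_b": y}, index=shared)
    return ConcordanceResult(n_variants=len(shared), pearson_r=r, pairs=pairs)


def concordance_permutation_p(
    result: ConcordanceResult, permutations: int = 999, seed: int = 0
) -> float:
    """One-sided permutation p for the observed positive correlation."""
    rng = substream(seed, "concordance-perm")
    x = result.pairs["freq_a"].to_numpy()
    y = result.pairs["freq_b"].to_numpy()
    obs = result.pearson_r
    count = 0
    for _ in range(permutations):
        r = np.corrcoef(x, rng.permutation(y))[0, 1]
        if r >= obs:
            count += 1
    return (1 + count) / (permutations + 1)
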