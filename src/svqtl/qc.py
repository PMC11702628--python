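"""Variant-level statistics, QC filters, LD statistics and PCA with an
automatic knee-point choice of the number of components.

The Hardy-Weinberg test is the exact conditional test: with the allele
counts fixed, the probability of each heterozygote count follows a
hypergeometric-type law, and the p-value sums the probabilities of all
configurations at most as probable as the observed one. The exact test is
preferred over the chi-square because SV genotype classes are often tiny.

Note on the filter direction: the QC list is stated as removing variants
with "HWE p-value > 0.001" in the source protocol, which is almost
certainly a transcription slip for the conventional p < 0.001 removal;
the conventional direction is the default here and the switch
``hwe_remove_low`` exposes the literal reading.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.decomposition import PCA

from .records import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

AUTOSOMES = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}


@dataclass
class VariantStats:
    allele_frequency: float
    minor_allele_frequency: float
    carrier_frequency: float
    call_rate: float
    hwe_p: float
    n_AA: int
    n_Aa: int
    n_aa: int
    n_missing: int


def variant_stats(dosages: np.ndarray) -> VariantStats:
    """Per-variant counts and frequencies from a dosage vector (-1 missing).

    Carrier frequency is the share of validly genotyped samples carrying
    at least one alternate allele; explicitly called 0/0 genotypes count
    in the denominator with frequency contribution zero.
    """
    d = np.asarray(dosages)
    n_missing = int((d == MISSING).sum())
    n_AA = int((d == 0).sum())
    n_Aa = int((d == 1).sum())
    n_aa = int((d == 2).sum())
    called = n_AA + n_Aa + n_aa
    if called == 0:
        raise ValueError("all genotypes missing")
    af = (n_Aa + 2 * n_aa) / (2 * called)
    return VariantStats(
        allele_frequency=af,
        minor_allele_frequency=min(af, 1 - af),
        carrier_frequency=(n_Aa + n_aa) / called,
        call_rate=called / d.size,
        hwe_p=hwe_exact_p(n_AA, n_Aa, n_aa),
        n_AA=n_AA,
        n_Aa=n_Aa,
        n_aa=n_aa,
        n_missing=n_missing,
    )


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Enumerates every heterozygote count with the observed allele counts
    (same parity) and sums the probabilities of those no more probable
    than the observed configuration.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("at least one genotype required")
    n_a = n_Aa + 2 * n_aa  # minor-agnostic: symmetric in A <-> a
    n_A = 2 * n - n_a
    rare = min(n_A, n_a)
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(het = h | allele counts) up to a constant:
    #   n! / (nAA! nAa! naa!) * 2^h with nAa=h, naa=(rare-h)/2, nAA=n-nAa-naa
    n_hom_rare = (rare - hets) // 2
    n_hom_common = n - hets - n_hom_rare
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(n_hom_rare + 1)
        - gammaln(n_hom_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[np.searchsorted(hets, n_Aa)]
    p = float(probs[probs <= obs * (1 + 1e-12)].sum())
    return min(p, 1.0)


@dataclass
class QCThresholds:
    maf_min: float = 0.05
    call_rate_min: float = 0.95
    hwe_alpha: float = 0.001
    hwe_remove_low: bool = True  # remove p < alpha (conventional direction)
    autosomes: frozenset = frozenset(AUTOSOMES)


def apply_qc_filters(
    gmat: GenotypeMatrix, thresholds: QCThresholds = QCThresholds()
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove variants failing MAF / call-rate / HWE / autosome rules.

    Returns the filtered matrix and an exclusion log listing every rule
    each removed variant failed.
    """
    if gmat.n_variants == 0:
        raise ValueError("empty genotype matrix")
    reasons: list[tuple[str, str]] = []
    keep = np.ones(gmat.n_variants, dtype=bool)
    for i, vid in enumerate(gmat.variants.index):
        d = gmat.dosages[i]
        failed = []
        if (d != MISSING).sum() == 0:
            failed.append("all_missing")
        else:
            st = variant_stats(d)
            if st.minor_allele_frequency < thresholds.maf_min:
                failed.append("MAF")
            if st.call_rate < thresholds.call_rate_min:
                failed.append("call_rate")
            hwe_bad = (
                st.hwe_p < thresholds.hwe_alpha
                if thresholds.hwe_remove_low
                else st.hwe_p > thresholds.hwe_alpha
            )
            if hwe_bad:
                failed.append("HWE")
        if gmat.variants.loc[vid, "chrom"] not in thresholds.autosomes:
            failed.append("autosome")
        if failed:
            keep[i] = False
            reasons.append((vid, ",".join(failed)))
    exclusions = pd.DataFrame(reasons, columns=["id", "reason"]).set_index("id")
    return gmat.subset_variants(keep), exclusions


# ---------------------------------------------------------------------------
# linkage disequilibrium


@dataclass
class LDPair:
    r_squared: float
    d_prime: float


def ld_stats(
    dosages_a: np.ndarray, dosages_b: np.ndarray, max_iter: int = 200
) -> LDPair:
    """r-squared and D' between two variants' dosage vectors.

    r^2 is the squared Pearson correlation of dosages over jointly
    non-missing samples; D' comes from EM-estimated haplotype frequencies
    normalized by the frequency-bound maximum |D|. Monomorphic input among
    the jointly called samples is an error.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        raise ValueError("monomorphic or empty input: LD undefined")
    r = np.corrcoef(a, b)[0, 1]

    # EM for haplotype frequencies of two biallelic loci
    pA = a.mean() / 2
    pB = b.mean() / 2
    f = np.array(  # fAB, fAb, faB, fab  (A/B = alternate alleles)
        [pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)]
    )
    f = np.clip(f, 1e-12, None)
    f /= f.sum()
    n = a.size
    counts = np.zeros((3, 3))
    for ga, gb in zip(a.astype(int), b.astype(int)):
        counts[ga, gb] += 1
    for _ in range(max_iter):
        fAB, fAb, faB, fab = f
        # expected haplotype counts; only the double het is ambiguous
        hap = np.zeros(4)
        for ga in range(3):
            for gb in range(3):
                c = counts[ga, gb]
                if c == 0:
                    continue
                if ga == 1 and gb == 1:
                    cis = fAB * fab
                    trans = fAb * faB
                    w = cis / (cis + trans)
                    hap += c * np.array([w, 1 - w, 1 - w, w])
                else:
                    nA, na = ga, 2 - ga
                    nB, nb = gb, 2 - gb
                    # unambiguous: alleles pair deterministically
                    hap[0] += c * min(nA, nB) if (nA and nB) else 0
                    hap[1] += c * min(nA, nb) if (nA and nb) else 0
                    hap[2] += c * min(na, nB) if (na and nB) else 0
                    hap[3] += c * min(na, nb) if (na and nb) else 0
        new = hap / (2 * n)
        new = np.clip(new, 1e-12, None)
        new /= new.sum()
        if np.abs(new - f).max() < 1e-12:
            f = new
            break
        f = new
    fAB = f[0]
    pA_h = f[0] + f[1]
    pB_h = f[0] + f[2]
    D = fAB - pA_h * pB_h
    if D >= 0:
        dmax = min(pA_h * (1 - pB_h), (1 - pA_h) * pB_h)
    else:
        dmax = min(pA_h * pB_h, (1 - pA_h) * (1 - pB_h))
    dprime = 0.0 if dmax <= 0 else min(abs(D) / dmax, 1.0)
    return LDPair(r_squared=float(r**2), d_prime=float(dprime))


# ---------------------------------------------------------------------------
# PCA with knee selection


@dataclass
class PCSelection:
    scores: np.ndarray  # samples x k
    explained_variance_ratio: np.ndarray
    k: int


def knee_point(curve: np.ndarray) -> int:
    """Discrete Kneedle: index (1-based) of maximum distance from the chord.

    The curve is normalized to the unit square and the vertical distance
    from the straight line joining its endpoints is maximized. A curve
    with no interior knee (distance never above ~0) falls back to 1 with
    a warning.
    """
    y = np.asarray(curve, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 components for knee detection")
    x = np.linspace(0.0, 1.0, y.size)
    rng_y = y[0] - y[-1]
    if rng_y == 0:
        warnings.warn("flat explained-variance curve; falling back to k=1")
        return 1
    yn = (y - y[-1]) / rng_y
    chord = 1.0 + x * (0.0 - 1.0)  # line from (0,1) to (1,0)
    dist = chord - yn  # decreasing convex curve dips below its chord
    best = int(np.argmax(dist))
    if dist[best] <= 1e-12:
        warnings.warn("no interior knee in explained-variance curve; using k=1")
        return 1
    return best + 1


def pca_with_knee(data: np.ndarray, max_components: int) -> PCSelection:
    """Standardized PCA with the component count chosen at the knee.

    ``data`` is samples x features; missing values are mean-imputed per
    feature, features are standardized to mean 0 / unit variance, and the
    number of retained components is the knee of the explained-variance
    curve.
    """
    if max_components < 3:
        raise ValueError("need at least 3 components for knee selection")
    X = np.array(data, dtype=float)
    col_mean = np.nanmean(X, axis=0)
    nan_idx = np.where(np.isnan(X))
    X[nan_idx] = np.take(col_mean, nan_idx[1])
    sd = X.std(axis=0)
    keep = sd > 0
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / X[:, keep].std(axis=0)
    ncomp = min(max_components, min(X.shape) - 1)
    if ncomp < 3:
        raise ValueError("matrix too small for 3 components")
    pca = PCA(n_components=ncomp, svd_solver="full")
    scores = pca.fit_transform(X)
    k = knee_point(pca.explained_variance_ratio_)
    return PCSelection(
        scores=scores[:, :k],
        explained_variance_ratio=pca.explained_variance_ratio_,
        k=k,
    )
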