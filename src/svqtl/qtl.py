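"""Cis-QTL mapping: normalization, cis-pair enumeration, nominal fits,
per-phenotype permutation calibration and Storey q-value significance.

Phenotypes are rank-based inverse-normal transformed and min-max scaled
to [0,1]; the transform is monotone, so effect-direction conclusions are
unchanged. Each phenotype's cis window spans +/- 1 Mb around its anchor
(TSS for genes, region start for methylation), inclusive at the boundary.
For each variant-phenotype pair, phenotype and dosage are residualized on
the covariates and the slope comes from the simple regression of
residuals, with the t-test on n - p_covariates - 2 degrees of freedom.

The permutation scheme mirrors the tensorQTL approach: per phenotype, B
permutations of the (residualized) phenotype record the maximum
association statistic over cis variants, and the empirical p for the
observed lead is (1 + #{permutation max >= observed max}) / (B + 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline
from statsmodels.stats.multitest import multipletests

from ._seeds import substream
from .records import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

CIS_WINDOW = 1_000_000


def normalize_phenotypes(
    values: pd.DataFrame, max_missing_frac: float = 0.25
) -> pd.DataFrame:
    """Rank-inverse-normal transform then min-max scale each phenotype row.

    Rows with more than ``max_missing_frac`` missing values are dropped;
    constant rows are dropped with a warning. Output rows span exactly
    [0, 1]; missing entries stay missing.
    """
    keep_rows = []
    out_rows = []
    for pid, row in values.iterrows():
        y = row.to_numpy(dtype=float)
        ok = ~np.isnan(y)
        if 1 - ok.mean() > max_missing_frac:
            continue
        if np.nanstd(y) == 0:
            warnings.warn(f"dropping constant phenotype {pid}")
            continue
        ranks = stats.rankdata(y[ok], method="average")
        z = stats.norm.ppf(ranks / (ok.sum() + 1))
        z = (z - z.min()) / (z.max() - z.min())
        y_out = np.full_like(y, np.nan)
        y_out[ok] = z
        keep_rows.append(pid)
        out_rows.append(y_out)
    return pd.DataFrame(out_rows, index=keep_rows, columns=values.columns)


def enumerate_cis_pairs(
    phenotype_meta: pd.DataFrame,
    variant_meta: pd.DataFrame,
    window: int = CIS_WINDOW,
) -> tuple[pd.DataFrame, list[str]]:
    """All variant-phenotype pairs within +/- window of the anchor.

    The boundary is inclusive. Returns ``(pairs, untestable)`` where
    untestable lists phenotypes with no variant in the window.
    """
    pairs = []
    untestable = []
    by_chrom = {
        chrom: sub.sort_values("start")
        for chrom, sub in variant_meta.groupby("chrom")
    }
    for pid, prow in phenotype_meta.iterrows():
        sub = by_chrom.get(prow["chrom"])
        if sub is None:
            untestable.append(pid)
            continue
        starts = sub["start"].to_numpy()
        lo = np.searchsorted(starts, prow["anchor"] - window, side="left")
        hi = np.searchsorted(starts, prow["anchor"] + window, side="right")
        if hi <= lo:
            untestable.append(pid)
            continue
        for vid in sub.index[lo:hi]:
            pairs.append((pid, vid))
    return (
        pd.DataFrame(pairs, columns=["phenotype_id", "variant_id"]),
        untestable,
    )


def _covariate_design(covariates: pd.DataFrame, samples: list[str]) -> np.ndarray:
    C = covariates.loc[samples].astype(float).to_numpy()
    X = np.column_stack([np.ones(len(samples)), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        cur = X[:, :1]
        for j, name in enumerate(covariates.columns):
            cand = np.column_stack([cur, X[:, j + 1]])
            if np.linalg.matrix_rank(cand) == cur.shape[1]:
                bad.append(name)
            else:
                cur = cand
        raise ValueError(f"rank-deficient covariates: collinear columns {bad}")
    return X


def _residualize(M: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of each column of M on the design X."""
    beta, *_ = np.linalg.lstsq(X, M, rcond=None)
    return M - X @ beta


def _impute_dosages(d: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages (rows = variants)."""
    d = d.astype(float)
    miss = d == MISSING
    if miss.any():
        called = np.where(miss, np.nan, d)
        means = np.nanmean(called, axis=1)
        d = np.where(miss, means[:, None], d)
    return d


@dataclass
class _PhenotypeFit:
    """Cached residualized data for one phenotype's cis scan."""

    variant_ids: list[str]
    y_resid: np.ndarray
    g_resid: np.ndarray  # samples x variants
    df: int


def fit_nominal(
    pairs: pd.DataFrame,
    phenotypes: pd.DataFrame,
    gmat: GenotypeMatrix,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Nominal associations for every cis pair.

    Returns a frame with beta, se, t, p_nominal per (phenotype, variant).
    """
    assoc = []
    var_index = gmat.variants.index
    for pid, sub in pairs.groupby("phenotype_id", sort=False):
        fit = _prepare_phenotype(
            pid, list(sub["variant_id"]), phenotypes, gmat, covariates
        )
        if fit is None:
            continue
        b, se, t, p = _scan(fit)
        for j, vid in enumerate(fit.variant_ids):
            assoc.append((pid, vid, b[j], se[j], t[j], p[j]))
    return pd.DataFrame(
        assoc, columns=["phenotype_id", "variant_id", "beta", "se", "t", "p_nominal"]
    )


def _prepare_phenotype(
    pid: str,
    variant_ids: list[str],
    phenotypes: pd.DataFrame,
    gmat: GenotypeMatrix,
    covariates: pd.DataFrame,
) -> _PhenotypeFit | None:
    y = phenotypes.loc[pid, gmat.samples].to_numpy(dtype=float)
    ok = ~np.isnan(y)
    samples = [s for s, o in zip(gmat.samples, ok) if o]
    if len(samples) < covariates.shape[1] + 3:
        return None
    X = _covariate_design(covariates, samples)
    rows = gmat.variants.index.get_indexer(variant_ids)
    G = _impute_dosages(gmat.dosages[rows][:, ok]).T  # samples x variants
    y_r = _residualize(y[ok][:, None], X)[:, 0]
    g_r = _residualize(G, X)
    df = len(samples) - X.shape[1] - 1  # n - p_covariates(incl. intercept) - slope
    return _PhenotypeFit(variant_ids=variant_ids, y_resid=y_r, g_resid=g_r, df=df)


def _scan(fit: _PhenotypeFit) -> tuple[np.ndarray, ...]:
    g, y = fit.g_resid, fit.y_resid
    gg = (g * g).sum(axis=0)
    gg = np.where(gg == 0, np.nan, gg)
    beta = (g * y[:, None]).sum(axis=0) / gg
    resid_ss = (y * y).sum() - beta**2 * gg
    sigma2 = np.maximum(resid_ss, 0) / fit.df
    se = np.sqrt(sigma2 / gg)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), fit.df)
    p = np.where(np.isnan(t), 1.0, np.clip(p, np.finfo(float).tiny, 1.0))
    return beta, se, t, p


def _max_r_to_p(r: np.ndarray, df: int) -> np.ndarray:
    """Two-sided nominal p of the |correlation| statistic at ``df``."""
    r = np.clip(np.asarray(r, dtype=float), 0, 1 - 1e-12)
    t = r * np.sqrt(df / (1 - r**2))
    return np.clip(2 * stats.t.sf(t, df), np.finfo(float).tiny, 1.0)


def permutation_adjust(
    associations: pd.DataFrame,
    phenotypes: pd.DataFrame,
    gmat: GenotypeMatrix,
    covariates: pd.DataFrame,
    permutations: int = 1000,
    seed: int = 0,
    beta_approx: bool = True,
) -> pd.DataFrame:
    """Per-phenotype empirical p for the lead association.

    Each phenotype consumes a named substream of the top-level seed, so
    results do not depend on scan order. The statistic is the maximum
    |correlation| of the residualized phenotype with its cis variants,
    which is monotone in max |t| at fixed degrees of freedom.

    ``p_empirical_raw`` is the add-one estimator, bounded below by
    1/(B+1). With ``beta_approx`` a Beta distribution is fitted by
    maximum likelihood to the permutation null of the lead nominal p and
    ``p_empirical`` is its CDF at the observed lead — the tail smoothing
    the established cis-QTL engines use so that genuine signals are not
    floored at the permutation resolution.
    """
    if permutations < 100:
        raise ValueError("need at least 100 permutations")
    rows = []
    for pid, sub in associations.groupby("phenotype_id", sort=False):
        fit = _prepare_phenotype(
            pid, list(sub["variant_id"]), phenotypes, gmat, covariates
        )
        if fit is None:
            continue
        g = fit.g_resid
        gn = g / np.where(
            np.linalg.norm(g, axis=0) == 0, np.nan, np.linalg.norm(g, axis=0)
        )
        y = fit.y_resid
        yn = y / np.linalg.norm(y)
        obs = np.nanmax(np.abs(yn @ gn))
        rng = substream(seed, f"perm:{pid}")
        n = y.size
        perm_idx = np.argsort(rng.random((permutations, n)), axis=1)
        Yp = yn[perm_idx]  # permutations x samples
        perm_max = np.nanmax(np.abs(Yp @ gn), axis=1)
        p_raw = (1 + int((perm_max >= obs - 1e-12).sum())) / (permutations + 1)
        p_emp = p_raw
        if beta_approx:
            df = fit.df
            p_perm = _max_r_to_p(perm_max, df)
            p_obs = float(_max_r_to_p(np.array([obs]), df)[0])
            try:
                a_hat, b_hat, _, _ = stats.beta.fit(
                    np.clip(p_perm, 1e-12, 1 - 1e-12), floc=0, fscale=1
                )
                p_emp = float(
                    np.clip(stats.beta.cdf(p_obs, a_hat, b_hat),
                            np.finfo(float).tiny, 1.0)
                )
            except Exception:  # degenerate permutation null
                p_emp = p_raw
        lead = _lead_variant(sub, gmat)
        rows.append((pid, lead, p_emp, p_raw))
    return pd.DataFrame(
        rows,
        columns=["phenotype_id", "lead_variant", "p_empirical",
                 "p_empirical_raw"],
    ).set_index("phenotype_id")


def _lead_variant(assoc: pd.DataFrame, gmat: GenotypeMatrix) -> str:
    sub = assoc.copy()
    sub["abs_beta"] = sub["beta"].abs()
    sub["start"] = gmat.variants.loc[sub["variant_id"], "start"].to_numpy()
    sub = sub.sort_values(
        ["p_nominal", "abs_beta", "start", "variant_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    return sub["variant_id"].iloc[0]


def storey_qvalues(p: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey q-values with the smoother pi0 estimate.

    pi0 is estimated over lambda in {0.05, ..., 0.95} with a cubic
    smoothing spline evaluated at the largest lambda, falling back to 1
    when the estimate leaves (0, 1].
    """
    p = np.asarray(p, dtype=float)
    n = p.size
    if pi0 is None:
        lam = np.arange(0.05, 0.96, 0.05)
        pi0_hat = np.array([(p > l).mean() / (1 - l) for l in lam])
        try:
            spline = UnivariateSpline(lam, pi0_hat, k=3)
            pi0 = float(spline(lam[-1]))
        except Exception:  # degenerate inputs
            pi0 = 1.0
        if not (0 < pi0 <= 1):
            pi0 = 1.0
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * n * ranked / np.arange(1, n + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0, 1)
    out = np.empty(n)
    out[order] = q
    return out


def declare_significant(
    leads: pd.DataFrame, alpha: float = 0.05, pi0: float | None = None
) -> pd.DataFrame:
    """Attach q-values to per-phenotype leads and flag significance.

    Storey q over the empirical p-values; with fewer than 10 phenotypes
    falls back to BH with a warning.
    """
    leads = leads.copy()
    p = leads["p_empirical"].to_numpy()
    if len(leads) < 10:
        warnings.warn("fewer than 10 phenotypes: falling back to BH correction")
        leads["q"] = multipletests(p, method="fdr_bh")[1] if len(leads) else []
    else:
        leads["q"] = storey_qvalues(p, pi0=pi0)
    leads["significant"] = leads["q"] < alpha
    return leads
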