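"""Single-causal statistical fine-mapping from summary statistics.

Following the CAVIAR model with causal set size 1: with z-scores z and
LD matrix Sigma, the null distribution of z is N(0, Sigma) and, when
variant i is causal with non-centrality prior scale s, the marginal
distribution is N(0, Sigma + s^2 Sigma_i Sigma_i^T) where Sigma_i is the
i-th column of Sigma. Each single-causal configuration gets a uniform
prior (loci arrive pre-selected as significant, so the no-causal
configuration is excluded) and the posterior causal probability of
variant i is the normalized configuration likelihood.

Candidate sets are the top 100 variants by nominal p, plus the best SV
when none of the top 100 is an SV and the locus contains one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .records import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class FineMapParams:
    n_candidates: int = 100
    prior_effect_scale: float = 5.2  # non-centrality prior SD
    ridge: float = 1e-6

    def __post_init__(self) -> None:
        if self.prior_effect_scale <= 0:
            raise ValueError("prior_effect_scale must be positive")
        if self.ridge < 0:
            raise ValueError("ridge must be non-negative")


def select_candidates(
    locus_associations: pd.DataFrame,
    is_sv: pd.Series,
    n_candidates: int = 100,
) -> pd.DataFrame:
    """Top-N candidates by ascending nominal p, plus the best SV if absent.

    Ties break on |beta| descending, then variant id. Loci containing no
    SV at all proceed SV-free.
    """
    sub = locus_associations.copy()
    sub["is_sv"] = is_sv.reindex(sub["variant_id"]).to_numpy()
    sub["abs_beta"] = sub["beta"].abs()
    sub = sub.sort_values(
        ["p_nominal", "abs_beta", "variant_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    top = sub.head(n_candidates)
    if not top["is_sv"].any() and sub["is_sv"].any():
        best_sv = sub[sub["is_sv"]].iloc[[0]]
        top = pd.concat([top, best_sv])
    return top.drop(columns="abs_beta").reset_index(drop=True)


def compute_ld_matrix(
    gmat: GenotypeMatrix, candidate_ids: list[str], ridge: float = 1e-6
) -> tuple[np.ndarray, list[str]]:
    """Pairwise dosage correlation of candidates, ridge-stabilized.

    Missing dosages are mean-imputed; monomorphic candidates are dropped
    with a warning. The ridge is added to the diagonal so perfect-LD
    duplicates keep the matrix invertible.
    """
    rows = gmat.variants.index.get_indexer(candidate_ids)
    D = gmat.dosages[rows].astype(float)
    miss = D == MISSING
    if miss.any():
        means = np.nanmean(np.where(miss, np.nan, D), axis=1)
        D = np.where(miss, means[:, None], D)
    sd = D.std(axis=1)
    keep = sd > 0
    dropped = [vid for vid, k in zip(candidate_ids, keep) if not k]
    if dropped:
        log.warning("dropping %d monomorphic candidates", len(dropped))
    kept = [vid for vid, k in zip(candidate_ids, keep) if k]
    C = np.corrcoef(D[keep])
    if C.ndim == 0:
        C = np.array([[1.0]])
    return C + ridge * np.eye(C.shape[0]), kept


def single_causal_posterior(
    z: np.ndarray, sigma: np.ndarray, params: FineMapParams = FineMapParams()
) -> pd.DataFrame:
    """Posterior causal probability for each candidate under |C| = 1.

    Returns a frame with columns ``rho`` (posterior, summing to 1) and
    ``rank`` (1 = most likely causal). Log-densities are computed via
    Cholesky factorization; a Sigma that is not positive definite after
    the ridge is an error.
    """
    z = np.asarray(z, dtype=float)
    m = z.size
    if sigma.shape != (m, m):
        raise ValueError("Sigma shape does not match z")
    s2 = params.prior_effect_scale**2
    loglik = np.empty(m)
    for i in range(m):
        col = sigma[:, i]
        cov = sigma + s2 * np.outer(col, col)
        try:
            chol = cho_factor(cov, lower=True)
        except np.linalg.LinAlgError as exc:
            raise ValueError("LD matrix not positive definite after ridge") from exc
        logdet = 2 * np.log(np.diag(chol[0])).sum()
        quad = z @ cho_solve(chol, z)
        loglik[i] = -0.5 * (logdet + quad)
    loglik -= loglik.max()
    rho = np.exp(loglik)
    rho /= rho.sum()
    order = np.lexsort((np.arange(m), -rho))
    rank = np.empty(m, dtype=int)
    rank[order] = np.arange(1, m + 1)
    return pd.DataFrame({"rho": rho, "rank": rank})


def finemap_locus(
    locus_associations: pd.DataFrame,
    gmat: GenotypeMatrix,
    is_sv: pd.Series,
    params: FineMapParams = FineMapParams(),
) -> pd.DataFrame:
    """Candidate selection + LD + posterior for one significant locus."""
    cands = select_candidates(locus_associations, is_sv, params.n_candidates)
    sigma, kept = compute_ld_matrix(
        gmat, list(cands["variant_id"]), ridge=params.ridge
    )
    cands = cands[cands["variant_id"].isin(kept)].reset_index(drop=True)
    z = (cands["beta"] / cands["se"]).to_numpy()
    post = single_causal_posterior(z, sigma, params)
    out = pd.concat([cands[["variant_id", "is_sv"]], post], axis=1)
    return out.sort_values("rank").reset_index(drop=True)


def flag_sv_led_loci(
    locus_results: dict[str, pd.DataFrame],
    kinds: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Flag loci whose top candidate is an SV.

    Returns ``(per_locus, summary)``: a per-locus frame with the SV-led
    flag and top variant, and the SV-led fraction per phenotype kind.
    """
    rows = []
    for locus, res in locus_results.items():
        top = res.loc[res["rank"] == 1].iloc[0]
        rows.append(
            (
                locus,
                kinds.get(locus, "all") if kinds else "all",
                bool(top["is_sv"]),
                top["variant_id"],
            )
        )
    df = pd.DataFrame(
        rows, columns=["locus", "kind", "sv_led", "top_variant"]
    ).set_index("locus")
    summary = df.groupby("kind")["sv_led"].agg(["sum", "count", "mean"])
    summary.columns = ["n_sv_led", "n_loci", "sv_led_fraction"]
    return df, summary
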