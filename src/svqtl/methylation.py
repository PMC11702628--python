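"""Methylation phenotype construction and age-association models.

Phenotype units are adaptive genome windows (>= 1 kb, extended until they
hold >= 50 CpGs), CpG islands, promoters (a 60 bp core padded by 1 kb on
each side) and gene bodies (the span of the isoform with the most exons).
Per sample, a region's value is the unweighted mean methylated fraction
over its CpGs with read coverage >= 5, requiring >= 10 qualifying CpGs.

Age models are ordinary least squares of region methylation on age with
post-mortem interval and sex as covariates, Benjamini-Hochberg corrected
within region kind. The "large effect" screen keeps regions whose total
methylation change across the cohort's age span exceeds 0.1 with an age
partial R^2 above 0.4 — a per-year slope of 0.1 would be impossible for
fractions over decades, so the slope threshold is applied to the change
over the observed span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .records import GenomicInterval, MethylRegion

log = logging.getLogger(__name__)

MIN_WINDOW_SPAN = 1000
MIN_WINDOW_CPGS = 50


def build_adaptive_windows(
    cpg_positions: dict[str, np.ndarray],
    min_span: int = MIN_WINDOW_SPAN,
    min_cpgs: int = MIN_WINDOW_CPGS,
) -> list[MethylRegion]:
    """Tile each chromosome with non-overlapping adaptive windows.

    Each window starts where the previous one ended (the first at the
    first CpG), spans at least ``min_span`` bp and extends rightward until
    it holds at least ``min_cpgs`` CpGs. Trailing CpGs insufficient for a
    full window are dropped.
    """
    out: list[MethylRegion] = []
    for chrom in sorted(cpg_positions):
        pos = np.asarray(cpg_positions[chrom])
        if pos.size and np.any(np.diff(pos) <= 0):
            raise ValueError(f"{chrom}: CpG positions must be strictly increasing")
        i = 0
        start = int(pos[0]) if pos.size else 0
        while pos.size - i >= min_cpgs:
            end = max(start + min_span, int(pos[i + min_cpgs - 1]) + 1)
            j = int(np.searchsorted(pos, end, side="left"))
            out.append(
                MethylRegion(
                    interval=GenomicInterval(chrom, start, end),
                    kind="window",
                    n_cpgs=int(j - i),
                )
            )
            start, i = end, j
    return out


def choose_representative_isoform(
    isoforms: list[tuple[GenomicInterval, int]]
) -> GenomicInterval:
    """Pick the isoform with the most exons (ties: longest span, lowest start)."""
    if not isoforms:
        raise ValueError("gene with zero isoforms")
    return max(
        isoforms, key=lambda it: (it[1], it[0].length, -it[0].start)
    )[0]


def build_region_catalog(
    promoter_cores: dict[str, GenomicInterval],
    gene_isoforms: dict[str, list[tuple[GenomicInterval, int]]],
    cgis: dict[str, GenomicInterval],
    promoter_pad: int = 1000,
) -> list[MethylRegion]:
    """Build the CGI / promoter / gene-body phenotype catalog.

    Promoter cores (60 bp in the source database) are extended by
    ``promoter_pad`` bp up- and downstream; gene bodies use the
    representative isoform's span; CGIs pass through.
    """
    out: list[MethylRegion] = []
    for name, core in promoter_cores.items():
        iv = GenomicInterval(
            core.chrom, max(0, core.start - promoter_pad), core.end + promoter_pad
        )
        out.append(MethylRegion(interval=iv, kind="promoter", name=name))
    for name, isoforms in gene_isoforms.items():
        iv = choose_representative_isoform(isoforms)
        out.append(MethylRegion(interval=iv, kind="gene_body", name=name))
    for name, iv in cgis.items():
        out.append(MethylRegion(interval=iv, kind="CGI", name=name))
    return out


def aggregate_methylation(
    tracks: dict[str, pd.DataFrame],
    regions: list[MethylRegion],
    min_cpgs: int = 10,
    min_reads: int = 5,
    max_missing_frac: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-CpG tracks into a regions x samples phenotype matrix.

    Per sample per region the value is the unweighted mean CpG fraction
    over CpGs with coverage >= ``min_reads``; the value is missing when
    fewer than ``min_cpgs`` CpGs qualify. Regions missing in more than
    ``max_missing_frac`` of samples are dropped globally. Returns
    ``(values, meta)`` with meta holding chrom / anchor / kind.
    """
    samples = list(tracks)
    mat = np.full((len(regions), len(samples)), np.nan)
    for j, sample in enumerate(samples):
        track = tracks[sample]
        for chrom, sub in track.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            frac = sub["fraction"].to_numpy()
            cov = sub["coverage"].to_numpy()
            ok = cov >= min_reads
            for i, region in enumerate(regions):
                if region.interval.chrom != chrom:
                    continue
                lo = np.searchsorted(pos, region.interval.start, side="left")
                hi = np.searchsorted(pos, region.interval.end, side="left")
                use = ok[lo:hi]
                if use.sum() >= min_cpgs:
                    mat[i, j] = frac[lo:hi][use].mean()
    values = pd.DataFrame(mat, index=[r.name for r in regions], columns=samples)
    meta = pd.DataFrame(
        {
            "chrom": [r.interval.chrom for r in regions],
            "anchor": [r.anchor for r in regions],
            "kind": [r.kind for r in regions],
        },
        index=values.index,
    )
    keep = values.isna().mean(axis=1) <= max_missing_frac
    return values[keep], meta[keep]


@dataclass
class AgeRegressionResult:
    region: str
    slope: float
    p: float
    r_squared: float
    q: float


def fit_age_models(
    values: pd.DataFrame,
    covariates: pd.DataFrame,
    kinds: pd.Series | None = None,
    min_samples: int = 10,
) -> pd.DataFrame:
    """OLS of region methylation on age with PMI and sex covariates.

    ``covariates`` must hold ``age`` plus any adjustment columns (e.g.
    ``pmi``, ``sex``), indexed by sample. Returns a per-region frame with
    the age slope (fraction per year), the age coefficient's p-value, the
    age partial R^2 and a BH q computed within region kind. Regions with
    constant methylation are skipped with a log message.
    """
    samples = [s for s in values.columns if s in covariates.index]
    cov = covariates.loc[samples].astype(float)
    if "age" not in cov.columns:
        raise ValueError("covariates must include an 'age' column")
    others = [c for c in cov.columns if c != "age"]
    X_full = np.column_stack(
        [np.ones(len(samples)), cov["age"].to_numpy()]
        + [cov[c].to_numpy() for c in others]
    )
    Y = values[samples].to_numpy(dtype=float)
    p_params = X_full.shape[1]
    rows = []
    complete = ~np.isnan(Y).any(axis=1)

    def _fit_one(y, X):
        n = y.size
        if n < min_samples or np.nanstd(y) == 0:
            return None
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        df = n - X.shape[1]
        if df <= 0:
            return None
        sigma2 = resid @ resid / df
        xtx_inv = np.linalg.pinv(X.T @ X)
        se = np.sqrt(sigma2 * xtx_inv[1, 1])
        if se == 0:
            t = np.inf if beta[1] != 0 else 0.0
            p = 0.0 if beta[1] != 0 else 1.0
        else:
            t = beta[1] / se
            p = 2 * stats.t.sf(abs(t), df)
        partial_r2 = (t * t) / (t * t + df) if np.isfinite(t) else 1.0
        return beta[1], max(p, np.finfo(float).tiny), partial_r2

    for i, region in enumerate(values.index):
        y = Y[i]
        if complete[i]:
            res = _fit_one(y, X_full)
        else:
            ok = ~np.isnan(y)
            res = _fit_one(y[ok], X_full[ok]) if ok.sum() >= min_samples else None
        if res is None:
            log.info("skipping region %s (constant or too few samples)", region)
            continue
        rows.append((region, *res))
    out = pd.DataFrame(rows, columns=["region", "slope", "p", "r_squared"])
    out = out.set_index("region")
    out["q"] = np.nan
    if kinds is None:
        kinds = pd.Series("window", index=out.index)
    for kind, idx in out.groupby(kinds.reindex(out.index)).groups.items():
        out.loc[idx, "q"] = multipletests(out.loc[idx, "p"], method="fdr_bh")[1]
    return out


def concordance_and_large_effects(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    age_span_a: float,
    age_span_b: float,
    q_threshold: float = 0.05,
    change_threshold: float = 0.1,
    r2_threshold: float = 0.4,
) -> tuple[pd.Index, pd.Index, pd.Index]:
    """Cross-cohort shared-significant and within-cohort large-effect sets.

    Shared: regions with q < threshold in both cohorts and the same slope
    sign. Large-effect (per cohort): |slope x age span| above the change
    threshold and age R^2 above the R^2 threshold. Differing catalogs are
    intersected with a warning.
    """
    common = results_a.index.intersection(results_b.index)
    if len(common) < max(len(results_a), len(results_b)):
        log.warning(
            "region catalogs differ between cohorts; intersecting (%d shared)",
            len(common),
        )
    a, b = results_a.loc[common], results_b.loc[common]
    shared = common[
        (a["q"] < q_threshold)
        & (b["q"] < q_threshold)
        & (np.sign(a["slope"]) == np.sign(b["slope"]))
    ]

    def _large(res, span):
        return res.index[
            (res["slope"].abs() * span > change_threshold)
            & (res["r_squared"] > r2_threshold)
        ]

    return shared, _large(results_a, age_span_a), _large(results_b, age_span_b)
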