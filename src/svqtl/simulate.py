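"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a two-cohort long-read brain study: LD-structured
diploid genotypes for SVs and small variants, two noisy SV "caller"
views (an assembly-based caller that cannot score its calls and a
read-based caller that may emit symbolic alleles), per-sample
per-haplotype assembly-coverage beds, gene expression with planted cis
effects, and CpG methylation with planted cis effects plus age trends.

Defaults mirror the study conditions: cohorts of 205 and 154 samples
with age ranges 15-96 and 18-85 years, an SV type mix of ~56% insertions
/ ~44% deletions / ~0.1% inversions with insertion-length modes near
300 bp (Alu) and 6 kb (LINE1), and a rare-heavy allele-frequency law
under which most SVs have MAF below 1%.

LD is modelled with a block-wise Gaussian copula: haplotype alleles
within a block share a latent Gaussian factor with correlation rho,
which directly controls the dosage r^2 downstream fine-mapping sees.
Methylation noise lives on the logit scale, keeping fractions in [0,1]
and reproducing the bimodal hyper/hypo distribution of real CpG calls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from ._seeds import substream
from .records import (
    ASSEMBLY_CALLER,
    MISSING,
    READ_CALLER,
    GenotypeMatrix,
    SVRecord,
)
from . import io as svio

BASES = np.array(list("ACGT"))


@dataclass
class CohortSpec:
    """Shape of one synthetic cohort."""

    name: str = "cohortA"
    n_samples: int = 205
    n_sv: int = 300
    n_snv: int = 1200
    chrom: str = "chr1"
    chrom_length: int = 10_000_000
    ld_block_length: int = 50_000
    within_block_correlation: float = 0.7
    af_beta: tuple[float, float] = (0.15, 1.5)  # rare-heavy law
    common_fraction: float = 0.3  # share drawn from Beta(2,4) instead
    age_range: tuple[float, float] = (15.0, 96.0)
    site_labels: tuple[str, ...] = ("SH", "UKY", "UMARY")
    sv_type_probs: tuple[float, float, float] = (0.56, 0.4388, 0.0012)

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_sv + self.n_snv, self.chrom_length) <= 0:
            raise ValueError("counts and lengths must be positive")
        if not (0 <= self.within_block_correlation < 1):
            raise ValueError("within_block_correlation must be in [0, 1)")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range min must be below max")

    @property
    def samples(self) -> list[str]:
        width = len(str(self.n_samples))
        return [f"{self.name}_s{i:0{width}d}" for i in range(self.n_samples)]


def hbcc_like(name: str = "cohortB") -> CohortSpec:
    """Second-cohort preset: smaller n, wider AF spectrum, younger ages."""
    return CohortSpec(
        name=name,
        n_samples=154,
        age_range=(18.0, 85.0),
        site_labels=("HBCC",),
        common_fraction=0.35,
    )


@dataclass
class CallerNoiseModel:
    """Observation noise applied when a caller reports a true SV."""

    breakpoint_jitter_sd: float = 30.0
    edit_rate: float = 0.05  # per-base substitution rate on INS sequences
    dropout: float = 0.1
    symbolic_prob: float = 0.0  # read caller only; DEL/INV lose their sequence
    quality_range: tuple[float, float] = (20.0, 60.0)  # read caller
    caller: str = READ_CALLER

    def __post_init__(self) -> None:
        for name in ("edit_rate", "dropout", "symbolic_prob"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.breakpoint_jitter_sd < 0:
            raise ValueError("breakpoint_jitter_sd must be >= 0")


def default_noise_models() -> dict[str, CallerNoiseModel]:
    """Two-caller default: quality-less assembly calls, symbolic-prone read calls."""
    return {
        ASSEMBLY_CALLER: CallerNoiseModel(caller=ASSEMBLY_CALLER),
        READ_CALLER: CallerNoiseModel(caller=READ_CALLER, symbolic_prob=0.3),
    }


@dataclass
class PlantedEffect:
    phenotype_id: str
    variant_id: str
    beta: float
    sigma: float
    kind: str  # expression | methylation


@dataclass
class TruthTable:
    """Generative truth downstream recovery is tested against."""

    effects: list[PlantedEffect] = field(default_factory=list)
    age_slopes: dict[str, float] = field(default_factory=dict)  # logit/yr

    def validate(self, variant_ids) -> None:
        known = set(variant_ids)
        for e in self.effects:
            if e.variant_id not in known:
                raise ValueError(f"planted effect on unknown variant {e.variant_id}")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "effects": [asdict(e) for e in self.effects],
                    "age_slopes": self.age_slopes,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            effects=[PlantedEffect(**e) for e in data["effects"]],
            age_slopes=data["age_slopes"],
        )


# ---------------------------------------------------------------------------
# genotypes


def _sv_lengths(rng: np.random.Generator, svtypes: np.ndarray) -> np.ndarray:
    """Signed SV lengths: INS bimodal near 300 bp / 6 kb; DEL negative."""
    n = svtypes.size
    lengths = np.empty(n, dtype=int)
    ins = svtypes == "INS"
    n_ins = int(ins.sum())
    mode = rng.random(n_ins) < 0.75
    ln = np.where(
        mode,
        rng.lognormal(np.log(300), 0.35, n_ins),
        rng.lognormal(np.log(6000), 0.35, n_ins),
    )
    lengths[ins] = np.clip(ln, 50, 60_000).astype(int)
    other = ~ins
    n_other = int(other.sum())
    lengths[other] = np.clip(
        rng.lognormal(np.log(400), 1.2, n_other), 50, 60_000
    ).astype(int)
    lengths[svtypes == "DEL"] *= -1
    return lengths


def simulate_genotypes(
    spec: CohortSpec, seed: int, catalog: pd.DataFrame | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw LD-structured diploid genotypes and the variant catalog.

    Haplotype alleles are thresholded Gaussians: within an LD block each
    haplotype shares one latent factor with loading sqrt(rho), so the
    pairwise latent correlation within a block is rho and cross-block
    variants are independent. The genotype is the sum of two haplotypes.

    The catalog carries, per variant: coordinates, type, signed length,
    insertion sequence, true allele frequency and an ``is_sv`` flag.
    Passing an existing ``catalog`` reuses its variants *and* allele
    frequencies with fresh haplotypes — the two-cohort scenario, where
    both cohorts segregate the same variants at shared frequencies.
    """
    rho = spec.within_block_correlation
    rng = substream(seed, f"genotypes:{spec.name}")
    if catalog is not None:
        positions = catalog["start"].to_numpy()
        af = catalog["af_true"].to_numpy()
        n_var = len(catalog)
        blocks = positions // spec.ld_block_length
        block_ids, block_idx = np.unique(blocks, return_inverse=True)
        n_hap = 2 * spec.n_samples
        u = rng.standard_normal((n_hap, block_ids.size))
        eps = rng.standard_normal((n_hap, n_var))
        z = np.sqrt(rho) * u[:, block_idx] + np.sqrt(1 - rho) * eps
        hap = (z < norm.ppf(af)[None, :]).astype(np.int16)
        dosages = (hap[0::2] + hap[1::2]).T
        gmat = GenotypeMatrix(
            dosages,
            catalog[["chrom", "start", "end", "svtype", "svlen", "is_sv"]],
            spec.samples,
        )
        return gmat, catalog.copy()
    n_var = spec.n_sv + spec.n_snv
    margin = min(70_000, max(1, spec.chrom_length // 10))  # keep spans on-chromosome
    positions = np.sort(
        rng.choice(
            np.arange(margin, spec.chrom_length - margin), size=n_var, replace=False
        )
    )
    is_sv = np.zeros(n_var, dtype=bool)
    is_sv[rng.choice(n_var, size=spec.n_sv, replace=False)] = True

    svtypes = np.where(is_sv, "", "SNV").astype(object)
    svtypes[is_sv] = rng.choice(
        ["INS", "DEL", "INV"], size=spec.n_sv, p=spec.sv_type_probs
    )
    svlen = np.zeros(n_var, dtype=int)
    svlen[is_sv] = _sv_lengths(rng, svtypes[is_sv])

    common = rng.random(n_var) < spec.common_fraction
    af = np.where(
        common,
        rng.beta(2.0, 4.0, n_var),
        rng.beta(*spec.af_beta, n_var),
    )
    af = np.clip(af, 0.5 / (2 * spec.n_samples), 0.99)

    blocks = positions // spec.ld_block_length
    block_ids, block_idx = np.unique(blocks, return_inverse=True)
    n_hap = 2 * spec.n_samples
    u = rng.standard_normal((n_hap, block_ids.size))
    eps = rng.standard_normal((n_hap, n_var))
    z = np.sqrt(rho) * u[:, block_idx] + np.sqrt(1 - rho) * eps
    hap = (z < norm.ppf(af)[None, :]).astype(np.int16)
    dosages = (hap[0::2] + hap[1::2]).T  # variants x samples

    ids = []
    seqs: list[str | None] = []
    for i in range(n_var):
        if not is_sv[i]:
            ids.append(f"snv_{spec.chrom}_{positions[i]}")
            seqs.append(None)
            continue
        start = int(positions[i])
        end = start if svtypes[i] == "INS" else start + abs(int(svlen[i]))
        ids.append(f"napu_{spec.chrom}_{start}_{end}_{svtypes[i]}_{svlen[i]}")
        if svtypes[i] == "INS":
            seqs.append("".join(rng.choice(BASES, size=int(svlen[i]))))
        else:
            seqs.append(None)
    ends = np.where(
        svtypes == "INS",
        positions,
        np.where(svtypes == "SNV", positions + 1, positions + np.abs(svlen)),
    ).astype(int)
    catalog = pd.DataFrame(
        {
            "chrom": spec.chrom,
            "start": positions,
            "end": ends,
            "svtype": svtypes,
            "svlen": svlen,
            "is_sv": is_sv,
            "af_true": af,
            "seq": seqs,
        },
        index=pd.Index(ids, name="id"),
    )
    gmat = GenotypeMatrix(
        dosages, catalog[["chrom", "start", "end", "svtype", "svlen", "is_sv"]],
        spec.samples,
    )
    return gmat, catalog


def simulate_reference(spec: CohortSpec, seed: int) -> dict[str, str]:
    """Random reference sequence for the synthetic chromosome."""
    rng = substream(seed, f"reference:{spec.name}")
    return {spec.chrom: "".join(rng.choice(BASES, size=spec.chrom_length))}


# ---------------------------------------------------------------------------
# caller observations


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0 or not seq:
        return seq
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    if hits.size:
        arr[hits] = BASES[
            (np.searchsorted(BASES, arr[hits]) + rng.integers(1, 4, hits.size)) % 4
        ]
    return "".join(arr)


def observe_caller_calls(
    catalog: pd.DataFrame,
    gmat: GenotypeMatrix,
    models: dict[str, CallerNoiseModel],
    seed: int,
    reference: dict[str, str] | None = None,
) -> dict[str, dict[str, list[SVRecord]]]:
    """Noisy per-sample, per-caller SV call sets from the truth catalog.

    Each true SV carried by a sample appears in a caller's call set with
    probability 1 - dropout, with its start jittered, its insertion
    sequence mutated at the per-base edit rate, and (read caller only)
    its DEL/INV alleles optionally symbolic (sequence-unresolved).
    Non-symbolic deletions carry their deleted reference bases when a
    reference is supplied. Assembly-caller quality is fixed at 0.
    Provenance encodes ``caller:sample:variant``.
    """
    sv_rows = np.flatnonzero(catalog["is_sv"].to_numpy())
    out: dict[str, dict[str, list[SVRecord]]] = {}
    for caller, model in models.items():
        rng = substream(seed, f"caller:{caller}")
        calls: dict[str, list[SVRecord]] = {s: [] for s in gmat.samples}
        for i in sv_rows:
            vid = catalog.index[i]
            row = catalog.iloc[i]
            carriers = np.flatnonzero(gmat.dosages[i] >= 1)
            for j in carriers:
                if rng.random() < model.dropout:
                    continue
                jitter = (
                    int(round(rng.normal(0, model.breakpoint_jitter_sd)))
                    if model.breakpoint_jitter_sd > 0
                    else 0
                )
                start = max(1, int(row["start"]) + jitter)
                svtype = row["svtype"]
                span = abs(int(row["svlen"]))
                end = start if svtype == "INS" else start + span
                seq = row["seq"]
                if svtype == "INS" and seq is not None:
                    seq = _mutate(seq, model.edit_rate, rng)
                symbolic = (
                    svtype in ("DEL", "INV")
                    and model.symbolic_prob > 0
                    and rng.random() < model.symbolic_prob
                )
                if caller == ASSEMBLY_CALLER:
                    quality = 0.0
                    symbolic = False
                else:
                    quality = float(
                        np.round(rng.uniform(*model.quality_range), 1)
                    )
                if svtype == "DEL" and not symbolic and reference is not None:
                    seq = reference[row["chrom"]][start:end]
                elif svtype != "INS":
                    seq = None
                sample = gmat.samples[j]
                rec = SVRecord(
                    chrom=row["chrom"],
                    start=start,
                    end=end,
                    svtype=svtype,
                    svlen=int(row["svlen"]),
                    seq=None if symbolic else seq,
                    quality=quality,
                    caller=caller,
                    genotypes={sample: int(gmat.dosages[i, j])},
                    provenance=(f"{caller}:{sample}:{vid}",),
                )
                calls[sample].append(rec)
        for s in calls:
            calls[s].sort(key=lambda r: (r.chrom, r.start, r.name))
        out[caller] = calls
    return out


# ---------------------------------------------------------------------------
# coverage beds


def simulate_coverage_beds(
    spec: CohortSpec, gap_rate: float, seed: int, tile: int = 10_000
) -> dict[str, dict[int, dict[str, list[tuple[int, int]]]]]:
    """Per-sample, per-haplotype covered intervals.

    The chromosome is tiled and each tile is independently uncovered with
    probability ``gap_rate``, so the expected uncovered fraction equals
    the gap rate exactly; adjacent covered tiles merge into one interval.
    """
    if not (0 <= gap_rate <= 1):
        raise ValueError("gap_rate must be in [0, 1]")
    rng = substream(seed, f"coverage:{spec.name}")
    n_tiles = int(np.ceil(spec.chrom_length / tile))
    out: dict[str, dict[int, dict[str, list[tuple[int, int]]]]] = {}
    for sample in spec.samples:
        haps = {}
        for h in (1, 2):
            if gap_rate == 0:
                haps[h] = {spec.chrom: [(0, spec.chrom_length)]}
                continue
            covered = rng.random(n_tiles) >= gap_rate
            intervals: list[tuple[int, int]] = []
            start = None
            for t in range(n_tiles):
                if covered[t] and start is None:
                    start = t * tile
                elif not covered[t] and start is not None:
                    intervals.append((start, t * tile))
                    start = None
            if start is not None:
                intervals.append((start, spec.chrom_length))
            haps[h] = {spec.chrom: intervals}
        out[sample] = haps
    return out


# ---------------------------------------------------------------------------
# phenotypes


def plant_expression_truth(
    catalog: pd.DataFrame,
    spec: CohortSpec,
    seed: int,
    n_genes: int = 100,
    n_qtl: int = 20,
    beta_sd: float = 0.6,
    beta_min: float = 0.2,
    sigma: float = 1.0,
    qtl_maf_min: float = 0.05,
    sv_qtl_fraction: float = 0.3,
) -> tuple[pd.DataFrame, TruthTable]:
    """Gene metadata (TSS anchors) plus planted cis effects.

    A fraction of the planted causal variants are SVs; causal variants
    are drawn among sufficiently common variants so they survive QC.
    """
    rng = substream(seed, f"expr-truth:{spec.name}")
    tss = np.sort(
        rng.choice(np.arange(10_000, spec.chrom_length - 10_000), n_genes, False)
    )
    meta = pd.DataFrame(
        {"chrom": spec.chrom, "anchor": tss},
        index=pd.Index([f"{spec.name}_gene{i:04d}" for i in range(n_genes)],
                       name="phenotype_id"),
    )
    maf = np.minimum(catalog["af_true"], 1 - catalog["af_true"])
    eligible = catalog[maf >= qtl_maf_min]
    effects = []
    gene_ids = list(meta.index)
    chosen_genes = rng.choice(len(gene_ids), size=min(n_qtl, n_genes), replace=False)
    for gi in np.sort(chosen_genes):
        pid = gene_ids[gi]
        anchor = meta.loc[pid, "anchor"]
        near = eligible[(eligible["start"] - anchor).abs() <= 900_000]
        if near.empty:
            continue
        pick_sv = rng.random() < sv_qtl_fraction
        pool = near[near["is_sv"]] if (pick_sv and near["is_sv"].any()) else near
        vid = pool.index[rng.integers(len(pool))]
        beta = float(rng.normal(0, beta_sd))
        if abs(beta) < beta_min:
            beta = beta_min * np.sign(beta) if beta != 0 else beta_min
        effects.append(
            PlantedEffect(pid, vid, beta=beta, sigma=sigma, kind="expression")
        )
    return meta, TruthTable(effects=effects)


def simulate_expression(
    gmat: GenotypeMatrix,
    meta: pd.DataFrame,
    truth: TruthTable,
    covariates: pd.DataFrame,
    seed: int,
    sigma: float = 1.0,
    covariate_effects: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Expression matrix: linear-in-dosage planted effects + Gaussian noise.

    ``y = beta_true * g + sum(covariate effects) + N(0, sigma^2)``; the
    per-phenotype noise SD from the truth table overrides ``sigma`` for
    phenotypes carrying a planted effect.
    """
    truth.validate(gmat.variants.index)
    rng = substream(seed, "expression")
    n = gmat.n_samples
    Y = pd.DataFrame(
        0.0, index=meta.index, columns=gmat.samples
    )
    noise_sd = pd.Series(sigma, index=meta.index)
    for e in truth.effects:
        if e.kind != "expression" or e.phenotype_id not in Y.index:
            continue
        row = gmat.variants.index.get_loc(e.variant_id)
        g = _impute_row(gmat.dosages[row])
        Y.loc[e.phenotype_id] += e.beta * g
        noise_sd.loc[e.phenotype_id] = e.sigma
    if covariate_effects:
        cov = covariates.loc[gmat.samples]
        for col, w in covariate_effects.items():
            Y += w * cov[col].to_numpy()[None, :]
    Y += rng.standard_normal(Y.shape) * noise_sd.to_numpy()[:, None]
    return Y


def _impute_row(d: np.ndarray) -> np.ndarray:
    d = d.astype(float)
    miss = d == MISSING
    if miss.any():
        d[miss] = d[~miss].mean() if (~miss).any() else 0.0
    return d


def simulate_covariates(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Sample covariates: age, sex, post-mortem interval, site dummies."""
    rng = substream(seed, f"covariates:{spec.name}")
    n = spec.n_samples
    age = np.round(rng.uniform(*spec.age_range, n), 1)
    sex = rng.integers(0, 2, n)
    pmi = np.round(rng.gamma(4.0, 3.0, n), 1)  # hours
    site = rng.integers(0, len(spec.site_labels), n)
    cov = pd.DataFrame(
        {"age": age, "sex": sex, "pmi": pmi},
        index=pd.Index(spec.samples, name="sample"),
    )
    for k, lab in enumerate(spec.site_labels[1:], start=1):
        cov[f"site_{lab}"] = (site == k).astype(int)
    return cov


def plant_methylation_truth(
    regions: list,
    catalog: pd.DataFrame,
    spec: CohortSpec,
    seed: int,
    n_mqtl: int = 10,
    n_age_regions: int = 20,
    age_slope_logit: float = 0.02,
    beta_logit_sd: float = 1.0,
    qtl_maf_min: float = 0.05,
) -> TruthTable:
    """Plant cis methylation effects and per-region age slopes (logit/yr)."""
    rng = substream(seed, f"meth-truth:{spec.name}")
    maf = np.minimum(catalog["af_true"], 1 - catalog["af_true"])
    eligible = catalog[maf >= qtl_maf_min]
    names = [r.name for r in regions]
    effects = []
    if n_mqtl and len(eligible):
        idx = rng.choice(len(regions), size=min(n_mqtl, len(regions)), replace=False)
        for i in np.sort(idx):
            region = regions[i]
            near = eligible[
                (eligible["start"] - region.anchor).abs() <= 900_000
            ]
            if near.empty:
                continue
            vid = near.index[rng.integers(len(near))]
            beta = float(rng.normal(0, beta_logit_sd))
            if abs(beta) < 0.5:
                beta = 0.5 * (1 if beta >= 0 else -1)
            effects.append(
                PlantedEffect(region.name, vid, beta=beta, sigma=0.5,
                              kind="methylation")
            )
    age_slopes = {}
    if n_age_regions:
        idx = rng.choice(
            len(names), size=min(n_age_regions, len(names)), replace=False
        )
        for i in np.sort(idx):
            age_slopes[names[i]] = age_slope_logit * (1 if rng.random() < 0.8 else -1)
    return TruthTable(effects=effects, age_slopes=age_slopes)


def simulate_cpg_positions(
    spec: CohortSpec, seed: int, n_clusters: int = 60, cluster_cpgs: int = 80
) -> dict[str, np.ndarray]:
    """CpG coordinates with dense (island-like) and sparse regions."""
    rng = substream(seed, f"cpgs:{spec.name}")
    pos = []
    centers = np.sort(
        rng.choice(np.arange(50_000, spec.chrom_length - 50_000), n_clusters, False)
    )
    for c in centers:
        # dense cluster: ~10 bp spacing
        offs = np.cumsum(rng.integers(5, 20, cluster_cpgs))
        pos.append(c + offs)
    # sparse background: ~700 bp spacing
    n_bg = spec.chrom_length // 700
    bg = np.sort(rng.choice(np.arange(1, spec.chrom_length), n_bg, False))
    pos.append(bg)
    allpos = np.unique(np.concatenate(pos))
    return {spec.chrom: allpos[allpos < spec.chrom_length]}


def simulate_methylation(
    gmat: GenotypeMatrix,
    cpg_positions: dict[str, np.ndarray],
    regions: list,
    truth: TruthTable,
    ages: pd.Series,
    seed: int,
    noise_sd_logit: float = 0.3,
    mean_coverage: float = 20.0,
) -> dict[str, pd.DataFrame]:
    """Per-sample CpG tracks with planted cis effects and age trends.

    Per CpG the methylated fraction is
    ``expit(baseline + slope * (age - midpoint) + beta * g + noise)``,
    clipped to [0,1] by construction of the logistic. Baselines are
    bimodal (most CpGs hypermethylated), echoing real brain methylomes.
    Effects planted on a region shift every CpG inside it.
    """
    truth.validate(gmat.variants.index)
    rng = substream(seed, "methylation")
    chrom = next(iter(cpg_positions))
    pos = cpg_positions[chrom]
    n_cpg = pos.size
    n = gmat.n_samples
    hyper = rng.random(n_cpg) < 0.8
    baseline = np.where(
        hyper, rng.normal(1.8, 0.5, n_cpg), rng.normal(-1.8, 0.5, n_cpg)
    )
    age_c = ages.loc[gmat.samples].to_numpy() - ages.loc[gmat.samples].mean()

    logits = np.tile(baseline[:, None], (1, n)).astype(float)
    region_by_name = {r.name: r for r in regions}
    for name, slope in truth.age_slopes.items():
        r = region_by_name.get(name)
        if r is None:
            continue
        lo, hi = np.searchsorted(pos, [r.interval.start, r.interval.end])
        logits[lo:hi] += slope * age_c[None, :]
    for e in truth.effects:
        if e.kind != "methylation":
            continue
        r = region_by_name.get(e.phenotype_id)
        if r is None:
            continue
        lo, hi = np.searchsorted(pos, [r.interval.start, r.interval.end])
        row = gmat.variants.index.get_loc(e.variant_id)
        g = _impute_row(gmat.dosages[row])
        logits[lo:hi] += e.beta * g[None, :]
    logits += rng.normal(0, noise_sd_logit, size=logits.shape)
    fracs = expit(logits)
    out = {}
    for j, sample in enumerate(gmat.samples):
        cov = rng.poisson(mean_coverage, n_cpg)
        out[sample] = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": pos,
                "coverage": cov,
                "fraction": np.round(fracs[:, j], 4),
            }
        )
    return out


# ---------------------------------------------------------------------------
# bundled cohort


@dataclass
class Cohort:
    spec: CohortSpec
    gmat: GenotypeMatrix
    catalog: pd.DataFrame
    reference: dict[str, str]
    caller_calls: dict[str, dict[str, list[SVRecord]]]
    coverage: dict
    covariates: pd.DataFrame
    expression: pd.DataFrame
    expression_meta: pd.DataFrame
    methylation: dict[str, pd.DataFrame]
    cpg_positions: dict[str, np.ndarray]
    truth: TruthTable


def generate_cohort(
    spec: CohortSpec,
    seed: int,
    noise_models: dict[str, CallerNoiseModel] | None = None,
    gap_rate: float = 0.05,
    n_genes: int = 100,
    n_eqtl: int = 20,
    n_mqtl: int = 10,
    n_age_regions: int = 20,
    eqtl_beta_sd: float = 0.6,
    eqtl_beta_min: float = 0.2,
    catalog: pd.DataFrame | None = None,
) -> Cohort:
    """Generate a full self-consistent cohort bundle.

    Passing a ``catalog`` from another cohort reuses its variant
    positions/alleles (fresh genotypes), which is how the two-cohort
    cross-merge scenario is built.
    """
    if noise_models is None:
        noise_models = default_noise_models()
    gmat, cat = simulate_genotypes(spec, seed, catalog=catalog)
    reference = simulate_reference(spec, seed)
    calls = observe_caller_calls(cat, gmat, noise_models, seed, reference=reference)
    coverage = simulate_coverage_beds(spec, gap_rate, seed)
    covariates = simulate_covariates(spec, seed)
    expr_meta, expr_truth = plant_expression_truth(
        cat, spec, seed, n_genes=n_genes, n_qtl=n_eqtl,
        beta_sd=eqtl_beta_sd, beta_min=eqtl_beta_min,
    )
    expression = simulate_expression(
        gmat, expr_meta, expr_truth, covariates, seed
    )
    cpgs = simulate_cpg_positions(spec, seed)
    from .methylation import build_adaptive_windows

    windows = build_adaptive_windows(cpgs)
    meth_truth = plant_methylation_truth(
        windows, cat, spec, seed, n_mqtl=n_mqtl, n_age_regions=n_age_regions
    )
    methylation = simulate_methylation(
        gmat, cpgs, windows, meth_truth, covariates["age"], seed
    )
    truth = TruthTable(
        effects=expr_truth.effects + meth_truth.effects,
        age_slopes=meth_truth.age_slopes,
    )
    return Cohort(
        spec=spec,
        gmat=gmat,
        catalog=cat,
        reference=reference,
        caller_calls=calls,
        coverage=coverage,
        covariates=covariates,
        expression=expression,
        expression_meta=expr_meta,
        methylation=methylation,
        cpg_positions=cpgs,
        truth=truth,
    )


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Emit the cohort as the plain-text fixture bundle io reads back."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = cohort.spec
    contigs = {spec.chrom: spec.chrom_length}
    vcf_dir = outdir / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    for caller, per_sample in cohort.caller_calls.items():
        for sample, records in per_sample.items():
            svio.write_sv_vcf(
                records,
                vcf_dir / f"{sample}.{caller}.vcf",
                [sample],
                contigs,
                caller=caller,
            )
    bed_dir = outdir / "coverage"
    bed_dir.mkdir(exist_ok=True)
    for sample, haps in cohort.coverage.items():
        for h, by_chrom in haps.items():
            rows = [
                (chrom, s, e)
                for chrom, ivs in by_chrom.items()
                for (s, e) in ivs
            ]
            svio.write_bed(
                pd.DataFrame(rows, columns=["chrom", "start", "end"]),
                bed_dir / f"{sample}.hap{h}.bed",
            )
    meth_dir = outdir / "methylation"
    meth_dir.mkdir(exist_ok=True)
    for sample, track in cohort.methylation.items():
        svio.write_bedmethyl(track, meth_dir / f"{sample}.bedmethyl")
    svio.write_fasta(cohort.reference, outdir / "reference.fa")
    svio.write_phenotype_tsv(
        cohort.expression, cohort.expression_meta, outdir / "expression.tsv"
    )
    svio.write_covariates_tsv(cohort.covariates, outdir / "covariates.tsv")
    svio.write_genotype_tsv(cohort.gmat, outdir / "genotypes.tsv")
    cohort.truth.to_json(outdir / "truth.json")
    cohort.catalog.to_csv(outdir / "catalog.tsv", sep="\t")
    with open(outdir / "spec.json", "w") as fh:
        json.dump(asdict(spec), fh, indent=1)
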