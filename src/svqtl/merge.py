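"""The SV harmonization engine.

Merging follows the Truvari-style greedy collapse: records are clustered
against a seed chosen in a deterministic priority order (quality
descending, then start ascending, then |svlen| descending), a record
joins a cluster only by direct comparison against the seed (no transitive
chaining), and the cluster is emitted with the seed's representation.
Because assembly-based calls carry quality 0 and read-based calls carry a
positive score, the read-based representation of a variant supported by
both callers survives cross-caller collapse.

Sequence similarity is ``1 - editdistance / max(len)`` and is compared
only for pairs of sequence-resolved insertions; deletions and inversions
merge on span and size alone (their content is reference-determined).
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib

from .records import ASSEMBLY_CALLER, GenomicInterval, SVRecord

log = logging.getLogger(__name__)


@dataclass
class MergeParams:
    """Thresholds for one collapse pass."""

    seq_similarity_min: float | None = 0.75
    size_similarity_min: float = 0.75
    refdist: int = 500
    max_sv_size: int | None = None
    type_strict: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.size_similarity_min <= 1):
            raise ValueError("size_similarity_min must be in (0, 1]")
        if self.seq_similarity_min is not None and not (
            0 < self.seq_similarity_min <= 1
        ):
            raise ValueError("seq_similarity_min must be in (0, 1]")
        if self.refdist <= 0:
            raise ValueError("refdist must be positive")


#: loose pass used to re-collapse residual multi-allelic loci: larger
#: reference distance, relaxed size ratio, no sequence or type conditions
LOOSE_PARAMS = MergeParams(
    seq_similarity_min=None,
    size_similarity_min=0.5,
    refdist=1000,
    type_strict=False,
)


@dataclass
class SimilarityReport:
    size_sim: float
    seq_sim: float | None  # None when not applicable
    breakpoint_distance: int
    type_compatible: bool


def seq_similarity(a: str, b: str) -> float:
    """1 - Levenshtein distance over the longer length."""
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def _reciprocal_overlap(a: SVRecord, b: SVRecord) -> float:
    ov = min(a.end, b.end) - max(a.start, b.start)
    span = max(a.end - a.start, b.end - b.start)
    if span <= 0:
        return 0.0
    return max(ov, 0) / span


def sv_similarity(a: SVRecord, b: SVRecord, params: MergeParams) -> SimilarityReport:
    """Pairwise comparison report; raises if the records are on different chromosomes."""
    if a.chrom != b.chrom:
        raise ValueError("sv_similarity requires records on the same chromosome")
    size_sim = min(abs(a.svlen), abs(b.svlen)) / max(abs(a.svlen), abs(b.svlen))
    seq_sim: float | None = None
    if (
        a.svtype == "INS"
        and b.svtype == "INS"
        and a.sequence_resolved
        and b.sequence_resolved
    ):
        seq_sim = seq_similarity(a.seq, b.seq)
    return SimilarityReport(
        size_sim=size_sim,
        seq_sim=seq_sim,
        breakpoint_distance=abs(a.start - b.start),
        type_compatible=(not params.type_strict) or a.svtype == b.svtype,
    )


def records_match(seed: SVRecord, rec: SVRecord, params: MergeParams) -> bool:
    """Does ``rec`` join a cluster seeded at ``seed`` under ``params``?"""
    if seed.chrom != rec.chrom:
        return False
    rep = sv_similarity(seed, rec, params)
    if not rep.type_compatible:
        return False
    if rep.breakpoint_distance > params.refdist:
        return False
    if seed.svtype == "INV" and rec.svtype == "INV":
        # inversions merge on reciprocal span overlap
        if _reciprocal_overlap(seed, rec) < params.size_similarity_min:
            return False
    elif rep.size_sim < params.size_similarity_min:
        return False
    if (
        params.seq_similarity_min is not None
        and rep.seq_sim is not None
        and rep.seq_sim < params.seq_similarity_min
    ):
        return False
    return True


def _seed_order(records: Sequence[SVRecord]) -> list[int]:
    return sorted(
        range(len(records)),
        key=lambda i: (
            -records[i].quality,
            records[i].start,
            -abs(records[i].svlen),
            records[i].chrom,
            records[i].name,
            records[i].caller,
        ),
    )


def _merge_cluster(seed: SVRecord, members: list[SVRecord]) -> SVRecord:
    """Emit the seed's representation with genotypes merged across members.

    The seed's genotype wins any conflict (logged); provenance is the
    sorted union of member provenance.
    """
    genotypes = dict(seed.genotypes)
    prov: set[str] = set(seed.provenance)
    for m in members:
        prov.update(m.provenance)
        for s, g in m.genotypes.items():
            if s in genotypes:
                if genotypes[s] != g:
                    log.info(
                        "genotype conflict at %s sample %s: keeping seed %d over %d",
                        seed.name, s, genotypes[s], g,
                    )
            else:
                genotypes[s] = g
    out = seed.copy()
    out.genotypes = genotypes
    out.provenance = tuple(sorted(prov))
    return out


def cluster_and_collapse(
    records: Iterable[SVRecord], params: MergeParams
) -> list[SVRecord]:
    """Greedy seed-based collapse of similar SV records.

    Records above ``params.max_sv_size`` (when set) pass through unmerged.
    The result is independent of the input order: seed priority and the
    within-cluster scan order depend only on record content.
    """
    records = list(records)
    passthrough: list[SVRecord] = []
    if params.max_sv_size is not None:
        mergeable = [r for r in records if abs(r.svlen) <= params.max_sv_size]
        passthrough = [r for r in records if abs(r.svlen) > params.max_sv_size]
        records = mergeable

    # per-chromosome position index for neighbour lookup
    by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_chrom.setdefault(r.chrom, []).append(i)
    chrom_sorted: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, idxs in by_chrom.items():
        idxs.sort(key=lambda i: (records[i].start, records[i].name, records[i].caller))
        chrom_sorted[chrom] = ([records[i].start for i in idxs], idxs)

    assigned = [False] * len(records)
    out: list[SVRecord] = []
    for si in _seed_order(records):
        if assigned[si]:
            continue
        seed = records[si]
        assigned[si] = True
        starts, idxs = chrom_sorted[seed.chrom]
        lo = bisect.bisect_left(starts, seed.start - params.refdist)
        hi = bisect.bisect_right(starts, seed.start + params.refdist)
        members: list[SVRecord] = []
        for j in range(lo, hi):
            rj = idxs[j]
            if assigned[rj]:
                continue
            if records_match(seed, records[rj], params):
                assigned[rj] = True
                members.append(records[rj])
        out.append(_merge_cluster(seed, members))
    out.extend(r.copy() for r in passthrough)
    out.sort(key=lambda r: (r.chrom, r.start, r.name))
    return out


def cluster_and_collapse_oracle(
    records: Sequence[SVRecord], params: MergeParams
) -> list[SVRecord]:
    """Exhaustive reference collapse for small inputs.

    Evaluates every pair similarity up front and applies the same seed
    ordering and no-chaining rule by direct set manipulation. Quadratic;
    used as the independent check of the indexed greedy implementation.
    """
    records = list(records)
    if params.max_sv_size is not None:
        big = [r for r in records if abs(r.svlen) > params.max_sv_size]
        records = [r for r in records if abs(r.svlen) <= params.max_sv_size]
    else:
        big = []
    match = {
        (i, j): records_match(records[i], records[j], params)
        for i in range(len(records))
        for j in range(len(records))
        if i != j and records[i].chrom == records[j].chrom
    }
    remaining = set(range(len(records)))
    out = []
    for si in _seed_order(records):
        if si not in remaining:
            continue
        remaining.discard(si)
        member_idx = sorted(
            (j for j in remaining if match.get((si, j), False)),
            key=lambda j: (records[j].start, records[j].name, records[j].caller),
        )
        remaining.difference_update(member_idx)
        out.append(_merge_cluster(records[si], [records[j] for j in member_idx]))
    out.extend(r.copy() for r in big)
    out.sort(key=lambda r: (r.chrom, r.start, r.name))
    return out


# ---------------------------------------------------------------------------
# cross-caller harmonization


def resolve_symbolic(
    records: Iterable[SVRecord], reference: Mapping[str, str] | None
) -> list[SVRecord]:
    """Replace symbolic DEL alleles with reference sequence content."""
    out = []
    for r in records:
        if r.svtype == "DEL" and not r.sequence_resolved:
            if reference is None or r.chrom not in reference:
                raise ValueError(
                    f"symbolic DEL {r.name} but no reference sequence available"
                )
            out.append(r.copy(seq=reference[r.chrom][r.start : r.end]))
        else:
            out.append(r.copy())
    return out


def harmonize_callers(
    assembly_set: Iterable[SVRecord],
    read_set: Iterable[SVRecord],
    reference: Mapping[str, str] | None,
    params: MergeParams,
) -> list[SVRecord]:
    """Union the two callers' collapsed sets into one representative set.

    Symbolic deletions are sequence-resolved from the reference, assembly
    qualities are forced to 0 (the assembly caller cannot score its
    calls), and the concatenation is collapsed so the higher-quality
    (read-based) representation survives wherever both callers describe
    one variant.
    """
    assembly = [r.copy(quality=0.0) for r in assembly_set]
    read = resolve_symbolic(read_set, reference)
    return cluster_and_collapse(assembly + read, params)


# ---------------------------------------------------------------------------
# coverage-based reference genotyping


def _covered(intervals: list[tuple[int, int]], start: int, end: int) -> bool:
    """Is [start, end) fully inside one covered interval? (intervals sorted)"""
    i = bisect.bisect_right(intervals, (start, float("inf"))) - 1
    return i >= 0 and intervals[i][0] <= start and end <= intervals[i][1]


def genotype_from_coverage(
    records: Iterable[SVRecord],
    coverage: Mapping[str, Mapping[int, Mapping[str, list[tuple[int, int]]]]],
    samples: Sequence[str],
) -> list[SVRecord]:
    """Assign 0/0 to missing genotypes licensed by assembly coverage.

    ``coverage[sample][haplotype][chrom]`` is a sorted list of covered
    (start, end) intervals. For each assembly-supported variant and each
    sample with a missing genotype, the genotype becomes 0/0 only when
    BOTH haplotype beds fully cover the variant span; non-missing
    genotypes are never altered. A sample absent from the bundle is an
    error.
    """
    out = []
    for r in records:
        assembly_supported = r.caller == ASSEMBLY_CALLER or any(
            p.startswith(f"{ASSEMBLY_CALLER}:") for p in r.provenance
        )
        rr = r.copy()
        if assembly_supported:
            s0, e0 = r.span
            for s in samples:
                if s in rr.genotypes:
                    continue
                if s not in coverage:
                    raise ValueError(f"sample {s} missing from coverage bundle")
                haps = coverage[s]
                ok = all(
                    _covered(haps[h].get(r.chrom, []), s0, e0) for h in (1, 2)
                )
                if ok:
                    rr.genotypes[s] = 0
        out.append(rr)
    return out


def collapse_multiallelic(
    records: Iterable[SVRecord], loose_params: MergeParams = LOOSE_PARAMS
) -> list[SVRecord]:
    """Re-collapse residual multi-allelic loci with loose thresholds.

    Records whose breakpoints fall within the loose reference distance are
    re-merged ignoring type compatibility and sequence similarity, so
    e.g. an insertion and a deletion representing one event at one locus
    combine into the higher-quality representation. Already single-allelic
    sets pass through unchanged (idempotence).
    """
    return cluster_and_collapse(records, loose_params)


def merge_cohorts(
    set_a: Iterable[SVRecord],
    set_b: Iterable[SVRecord],
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    params: MergeParams,
) -> list[SVRecord]:
    """Cross-cohort collapse into a unified variant set.

    Variants larger than ``params.max_sv_size`` are exempt from merging.
    Sample name sets must be disjoint; genotypes stay missing for samples
    absent from a variant's source cohort unless later coverage-assigned.
    """
    overlap = set(samples_a) & set(samples_b)
    if overlap:
        raise ValueError(f"overlapping sample names between cohorts: {sorted(overlap)[:5]}")
    if params.max_sv_size is None:
        raise ValueError("cross-cohort merge requires max_sv_size")
    return cluster_and_collapse(list(set_a) + list(set_b), params)


# ---------------------------------------------------------------------------
# gene-context annotation


@dataclass
class GeneModel:
    """Protein-coding gene with exon / CDS / UTR intervals."""

    name: str
    span: GenomicInterval
    exons: list[GenomicInterval]
    cds: list[GenomicInterval]
    utr5: list[GenomicInterval]
    utr3: list[GenomicInterval]

    def __post_init__(self) -> None:
        for iv in [*self.exons, *self.cds, *self.utr5, *self.utr3]:
            if not (
                iv.chrom == self.span.chrom
                and self.span.start <= iv.start
                and iv.end <= self.span.end
            ):
                raise ValueError(
                    f"gene {self.name}: feature {iv} outside gene span {self.span}"
                )


def annotate_gene_context(
    svs: Iterable[SVRecord], genes: Sequence[GeneModel]
) -> dict[str, set[str]]:
    """Label each gene-intersecting SV with {intronic, coding, 5'UTR, 3'UTR}.

    Categories are not mutually exclusive; ``intronic`` means the SV
    intersects the gene but no exon. SVs that intersect no gene are absent
    from the result.
    """

    def _hits(iv_list, chrom, s, e):
        return any(iv.chrom == chrom and iv.start < e and s < iv.end for iv in iv_list)

    out: dict[str, set[str]] = {}
    for r in svs:
        s, e = r.span
        cats: set[str] = set()
        for g in genes:
            if not (g.span.chrom == r.chrom and g.span.start < e and s < g.span.end):
                continue
            if _hits(g.cds, r.chrom, s, e):
                cats.add("coding")
            if _hits(g.utr5, r.chrom, s, e):
                cats.add("5'UTR")
            if _hits(g.utr3, r.chrom, s, e):
                cats.add("3'UTR")
            if not _hits(g.exons, r.chrom, s, e):
                cats.add("intronic")
        if cats:
            out[r.name] = cats
    return out
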