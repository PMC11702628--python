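import itertools

import numpy as np
import pytest

from svqtl.merge import (
    GeneModel,
    LOOSE_PARAMS,
    MergeParams,
    annotate_gene_context,
    cluster_and_collapse,
    cluster_and_collapse_oracle,
    collapse_multiallelic,
    genotype_from_coverage,
    harmonize_callers,
    merge_cohorts,
    seq_similarity,
    sv_similarity,
)
from svqtl.records import GenomicInterval

from conftest import make_sv


def _levenshtein(a: str, b: str) -> int:
    """Plain dynamic-programming edit distance (independent oracle)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


class TestSimilarity:
    def test_identical_records(self):
        a = make_sv(1000, "INS", 300, seq="random")
        rep = sv_similarity(a, a, MergeParams())
        assert rep.size_sim == 1.0
        assert rep.seq_sim == 1.0
        assert rep.breakpoint_distance == 0

    def test_size_similarity_is_length_ratio(self):
        a = make_sv(1000, "INS", 300, seq=None)
        b = make_sv(1000, "INS", 400, seq=None)
        rep = sv_similarity(a, b, MergeParams())
        assert rep.size_sim == pytest.approx(300 / 400)
        assert rep.seq_sim is None  # unresolved sequences: inapplicable

    def test_sequence_similarity_single_substitution(self):
        a = make_sv(1000, "INS", 64, seq="ACGTACGT" * 8)
        b_seq = "ACGTACGT" * 7 + "ACGTACGA"
        b = make_sv(1000, "INS", 64, seq=b_seq)
        rep = sv_similarity(a, b, MergeParams())
        assert rep.seq_sim == pytest.approx(1 - 1 / 64)
        assert _levenshtein(a.seq, b.seq) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_seq_similarity_matches_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), size=60))
        b = "".join(rng.choice(list("ACGT"), size=rng.integers(50, 80)))
        expected = 1 - _levenshtein(a, b) / max(len(a), len(b))
        assert seq_similarity(a, b) == pytest.approx(expected)

    def test_different_chromosomes_error(self):
        a = make_sv(1000, "DEL", 100)
        b = make_sv(1000, "DEL", 100, chrom="chr2")
        with pytest.raises(ValueError):
            sv_similarity(a, b, MergeParams())


class TestClusterAndCollapse:
    def test_identical_records_from_two_samples_merge(self):
        a = make_sv(1000, "DEL", 500, genotypes={"s1": 1})
        b = make_sv(1000, "DEL", 500, genotypes={"s2": 2})
        out = cluster_and_collapse([a, b], MergeParams())
        assert len(out) == 1
        assert out[0].genotypes == {"s1": 1, "s2": 2}

    def test_distant_records_stay_apart(self):
        a = make_sv(1_000_000, "DEL", 500)
        b = make_sv(11_000_000, "DEL", 500)
        assert len(cluster_and_collapse([a, b], MergeParams())) == 2

    def test_chain_resolves_through_highest_quality_seed(self):
        # A~B and B~C but A and C too dissimilar directly; B has top quality
        # so the greedy pass seeds at B and absorbs both.
        a = make_sv(1000, "DEL", 80, quality=10, genotypes={"s1": 1})
        b = make_sv(1020, "DEL", 100, quality=60, genotypes={"s2": 1})
        c = make_sv(1040, "DEL", 130, quality=5, genotypes={"s3": 1})
        params = MergeParams(size_similarity_min=0.75)
        assert sv_similarity(a, b, params).size_sim >= 0.75
        assert sv_similarity(b, c, params).size_sim >= 0.75
        assert sv_similarity(a, c, params).size_sim < 0.75
        out = cluster_and_collapse([a, b, c], params)
        assert len(out) == 1
        assert out[0].start == b.start and out[0].quality == 60
        assert out[0].genotypes == {"s1": 1, "s2": 1, "s3": 1}

    def test_idempotence(self):
        rng = np.random.default_rng(3)
        records = [
            make_sv(int(p), "DEL", int(l), quality=float(q),
                    genotypes={f"s{i%5}": 1})
            for i, (p, l, q) in enumerate(
                zip(rng.integers(1000, 500_000, 60),
                    rng.integers(50, 5000, 60),
                    rng.integers(0, 60, 60))
            )
        ]
        once = cluster_and_collapse(records, MergeParams())
        twice = cluster_and_collapse(once, MergeParams())
        assert twice == once

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        records = [
            make_sv(int(p), "INS", int(l), seq="random", quality=float(q))
            for p, l, q in zip(rng.integers(1000, 100_000, 40),
                               rng.integers(50, 400, 40),
                               rng.integers(0, 60, 40))
        ]
        base = cluster_and_collapse(records, MergeParams())
        for perm_seed in range(3):
            perm = list(np.random.default_rng(perm_seed).permutation(len(records)))
            assert cluster_and_collapse([records[i] for i in perm],
                                        MergeParams()) == base

    def test_matches_exhaustive_oracle_on_random_instances(self):
        for seed in range(30):
            records = _random_instance(seed, n_max=30)
            params = MergeParams()
            assert cluster_and_collapse(records, params) == \
                cluster_and_collapse_oracle(records, params)


def _random_instance(seed, n_max=30):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, n_max + 1))
    records = []
    for i in range(n):
        svtype = rng.choice(["INS", "DEL", "INV"], p=[0.5, 0.4, 0.1])
        svlen = int(rng.integers(50, 2000))
        start = int(rng.integers(1000, 20_000))
        seq = None
        if svtype == "INS" and rng.random() < 0.7:
            seq = "".join(rng.choice(list("ACGT"), size=svlen))
        records.append(
            make_sv(start, svtype, svlen, seq=seq,
                    quality=float(rng.integers(0, 61)),
                    genotypes={f"s{int(rng.integers(0, 8))}": 1})
        )
    return records


class TestHarmonizeCallers:
    def test_read_representation_wins_on_shared_variant(self):
        asm = make_sv(5000, "DEL", 1000, quality=0, caller="assembly",
                      genotypes={"s1": 1})
        rd = make_sv(5010, "DEL", 1005, quality=60, caller="read",
                     genotypes={"s1": 1})
        ref = {"chr1": "A" * 10_000}
        out = harmonize_callers([asm], [rd], ref, MergeParams())
        assert len(out) == 1
        assert out[0].start == 5010  # read-based coordinates survive
        callers = {p.split(":")[0] for p in out[0].provenance}
        assert callers == {"assembly", "read"}

    def test_assembly_only_variant_survives_with_zero_quality(self):
        asm = make_sv(5000, "INS", 300, seq="random", quality=17,
                      caller="assembly")
        out = harmonize_callers([asm], [], None, MergeParams())
        assert len(out) == 1
        assert out[0].quality == 0.0  # assembly caller cannot score calls

    def test_disjoint_sets_concatenate(self):
        asm = [make_sv(5000, "INS", 300, seq="random", caller="assembly")]
        rd = [make_sv(50_000, "DEL", 700, quality=40, caller="read",
                      seq="A" * 700)]
        out = harmonize_callers(asm, rd, None, MergeParams())
        assert len(out) == 2

    def test_symbolic_del_resolved_from_reference(self):
        rd = make_sv(100, "DEL", 60, quality=40, caller="read")
        ref = {"chr1": "ACGT" * 1000}
        (out,) = harmonize_callers([], [rd], ref, MergeParams())
        assert out.sequence_resolved and out.seq == ref["chr1"][100:160]

    def test_symbolic_del_without_reference_errors(self):
        rd = make_sv(100, "DEL", 60, quality=40, caller="read")
        with pytest.raises(ValueError, match="reference"):
            harmonize_callers([], [rd], None, MergeParams())


class TestGenotypeFromCoverage:
    def _coverage(self, intervals):
        return {"s1": {1: {"chr1": intervals}, 2: {"chr1": intervals}}}

    def test_missing_with_double_coverage_becomes_homref(self):
        rec = make_sv(5000, "DEL", 500, caller="assembly", genotypes={})
        (out,) = genotype_from_coverage(
            [rec], self._coverage([(0, 100_000)]), ["s1"]
        )
        assert out.genotypes == {"s1": 0}

    def test_missing_without_coverage_stays_missing(self):
        rec = make_sv(5000, "DEL", 500, caller="assembly", genotypes={})
        (out,) = genotype_from_coverage(
            [rec], self._coverage([(0, 4000)]), ["s1"]
        )
        assert "s1" not in out.genotypes

    def test_one_haplotype_covered_is_not_enough(self):
        rec = make_sv(5000, "DEL", 500, caller="assembly", genotypes={})
        cov = {"s1": {1: {"chr1": [(0, 100_000)]}, 2: {"chr1": []}}}
        (out,) = genotype_from_coverage([rec], cov, ["s1"])
        assert "s1" not in out.genotypes

    def test_existing_genotype_never_altered(self):
        rec = make_sv(5000, "DEL", 500, caller="assembly",
                      genotypes={"s1": 1})
        (out,) = genotype_from_coverage(
            [rec], self._coverage([(0, 100_000)]), ["s1"]
        )
        assert out.genotypes == {"s1": 1}

    def test_read_only_variant_not_reference_genotyped(self):
        rec = make_sv(5000, "DEL", 500, caller="read", quality=50,
                      genotypes={})
        (out,) = genotype_from_coverage(
            [rec], self._coverage([(0, 100_000)]), ["s1"]
        )
        assert "s1" not in out.genotypes

    def test_sample_absent_from_bundle_errors(self):
        rec = make_sv(5000, "DEL", 500, caller="assembly", genotypes={})
        with pytest.raises(ValueError, match="s2"):
            genotype_from_coverage([rec], self._coverage([(0, 9000)]),
                                   ["s1", "s2"])


class TestCollapseMultiallelic:
    def test_same_locus_dels_within_loose_size_merge(self):
        a = make_sv(10_000, "DEL", 5000, quality=50, genotypes={"s1": 1})
        b = make_sv(10_000, "DEL", 3200, quality=10, genotypes={"s2": 1})
        # 3200/5000 = 0.64: fails the strict 0.75 cut, passes the loose 0.5
        assert len(cluster_and_collapse([a, b], MergeParams())) == 2
        out = collapse_multiallelic([a, b])
        assert len(out) == 1 and out[0].quality == 50

    def test_ins_and_del_at_same_locus_combine(self):
        ins = make_sv(10_000, "INS", 1382, seq="random", quality=60,
                      genotypes={"s1": 1})
        dele = make_sv(10_050, "DEL", 1090, quality=20, genotypes={"s2": 1})
        out = collapse_multiallelic([ins, dele])
        assert len(out) == 1
        assert out[0].svtype == "INS"  # higher-quality representation kept

    def test_single_allelic_set_unchanged(self):
        records = [
            make_sv(10_000, "DEL", 500, quality=30, genotypes={"s1": 1}),
            make_sv(40_000, "INS", 300, seq="random", quality=20),
        ]
        assert collapse_multiallelic(records) == sorted(
            (r.copy() for r in records), key=lambda r: r.start
        )


class TestMergeCohorts:
    def test_identical_variant_across_cohorts_unifies(self):
        a = make_sv(5000, "DEL", 800, quality=40, genotypes={"a1": 1})
        b = make_sv(5000, "DEL", 800, quality=40, genotypes={"b1": 2})
        out = merge_cohorts([a], [b], ["a1"], ["b1"],
                            MergeParams(max_sv_size=60_000))
        assert len(out) == 1
        assert out[0].genotypes == {"a1": 1, "b1": 2}

    def test_size_exemption_keeps_large_variants_apart(self):
        a = make_sv(5000, "DEL", 70_000, quality=40, genotypes={"a1": 1})
        b = make_sv(5000, "DEL", 70_000, quality=40, genotypes={"b1": 1})
        out = merge_cohorts([a], [b], ["a1"], ["b1"],
                            MergeParams(max_sv_size=60_000))
        assert len(out) == 2

    def test_overlapping_sample_names_rejected(self):
        a = make_sv(5000, "DEL", 800, genotypes={"s1": 1})
        with pytest.raises(ValueError, match="overlap"):
            merge_cohorts([a], [a], ["s1"], ["s1"],
                          MergeParams(max_sv_size=60_000))

    def test_cohort_private_variant_keeps_other_cohort_missing(self):
        a = make_sv(5000, "DEL", 800, quality=40, genotypes={"a1": 1})
        out = merge_cohorts([a], [], ["a1"], ["b1"],
                            MergeParams(max_sv_size=60_000))
        assert "b1" not in out[0].genotypes


class TestConservation:
    def test_genotyped_samples_never_lost_by_collapse(self):
        for seed in range(10):
            records = _random_instance(seed)
            out = cluster_and_collapse(records, MergeParams())
            in_samples = set()
            for r in records:
                in_samples.update(r.genotypes)
            out_samples = set()
            for r in out:
                out_samples.update(r.genotypes)
            assert in_samples == out_samples
            # every input record's samples appear in the cluster it joined
            prov_to_out = {}
            for r in out:
                for p in r.provenance:
                    prov_to_out[p] = r
            for r in records:
                target = prov_to_out[r.provenance[0]]
                assert set(r.genotypes) <= set(target.genotypes)


class TestAnnotateGeneContext:
    def _gene(self):
        iv = GenomicInterval
        return GeneModel(
            name="G1",
            span=iv("chr1", 10_000, 30_000),
            exons=[iv("chr1", 10_000, 10_500), iv("chr1", 20_000, 20_800),
                   iv("chr1", 29_000, 30_000)],
            cds=[iv("chr1", 10_200, 10_500), iv("chr1", 20_000, 20_800)],
            utr5=[iv("chr1", 10_000, 10_200)],
            utr3=[iv("chr1", 29_000, 30_000)],
        )

    def test_sv_inside_intron(self):
        sv = make_sv(15_000, "DEL", 500)
        assert annotate_gene_context([sv], [self._gene()]) == {
            sv.name: {"intronic"}
        }

    def test_sv_spanning_exon_boundary_is_coding(self):
        sv = make_sv(19_900, "DEL", 300)
        cats = annotate_gene_context([sv], [self._gene()])[sv.name]
        assert "coding" in cats and "intronic" not in cats

    def test_del_covering_utr5_and_first_cds(self):
        sv = make_sv(10_100, "DEL", 300)  # spans [10100, 10400)
        cats = annotate_gene_context([sv], [self._gene()])[sv.name]
        assert cats == {"coding", "5'UTR"}

    def test_intergenic_sv_absent_from_result(self):
        sv = make_sv(500_000, "DEL", 500)
        assert annotate_gene_context([sv], [self._gene()]) == {}

    def test_malformed_gene_model_rejected(self):
        iv = GenomicInterval
        with pytest.raises(ValueError):
            GeneModel(
                name="bad",
                span=iv("chr1", 10_000, 20_000),
                exons=[iv("chr1", 25_000, 26_000)],
                cds=[], utr5=[], utr3=[],
            )
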