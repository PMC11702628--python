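import numpy as np
import pandas as pd
import pytest

from svqtl.records import MISSING
from svqtl.simulate import (
    CallerNoiseModel,
    CohortSpec,
    PlantedEffect,
    TruthTable,
    default_noise_models,
    observe_caller_calls,
    plant_expression_truth,
    simulate_coverage_beds,
    simulate_covariates,
    simulate_cpg_positions,
    simulate_expression,
    simulate_genotypes,
    simulate_methylation,
)


def _small_spec(**kw):
    defaults = dict(
        name="t", n_samples=50, n_sv=30, n_snv=70, chrom_length=2_000_000
    )
    defaults.update(kw)
    return CohortSpec(**defaults)


class TestSpecValidation:
    def test_rho_bounds(self):
        with pytest.raises(ValueError):
            _small_spec(within_block_correlation=1.0)
        with pytest.raises(ValueError):
            _small_spec(within_block_correlation=-0.1)

    def test_age_range_order(self):
        with pytest.raises(ValueError):
            _small_spec(age_range=(90, 20))

    def test_noise_model_probability_bounds(self):
        with pytest.raises(ValueError):
            CallerNoiseModel(dropout=1.5)
        with pytest.raises(ValueError):
            CallerNoiseModel(breakpoint_jitter_sd=-1)


class TestGenotypes:
    def test_same_seed_identical_matrices(self):
        spec = _small_spec()
        g1, c1 = simulate_genotypes(spec, 11)
        g2, c2 = simulate_genotypes(spec, 11)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)
        pd.testing.assert_frame_equal(c1, c2)

    def test_zero_rho_gives_near_zero_correlations(self):
        spec = _small_spec(
            n_samples=500, n_sv=0, n_snv=40, within_block_correlation=0.0,
            common_fraction=1.0,
        )
        gmat, _ = simulate_genotypes(spec, 3)
        D = gmat.dosages.astype(float)
        keep = D.std(axis=1) > 0.2
        C = np.corrcoef(D[keep])
        off = C[~np.eye(keep.sum(), dtype=bool)]
        assert np.abs(off).max() < 0.2
        assert np.abs(off).mean() < 0.05

    def test_high_rho_raises_within_block_correlation(self):
        spec = _small_spec(
            n_samples=500, n_sv=0, n_snv=60, within_block_correlation=0.9,
            ld_block_length=2_000_000, common_fraction=1.0,
        )
        gmat, cat = simulate_genotypes(spec, 4)
        D = gmat.dosages.astype(float)
        keep = D.std(axis=1) > 0.3
        C = np.corrcoef(D[keep])
        off = C[~np.eye(keep.sum(), dtype=bool)]
        assert np.median(np.abs(off)) > 0.4

    def test_planted_frequency_within_three_binomial_sd(self):
        # binomial oracle: AF_hat ~ Binomial(2n, p)/2n
        spec = _small_spec(n_samples=500, n_sv=0, n_snv=1,
                           within_block_correlation=0.0)
        gmat, cat = simulate_genotypes(spec, 5)
        p = cat["af_true"].iloc[0]
        n_alleles = 2 * 500
        af_hat = gmat.dosages.sum() / n_alleles
        sd = np.sqrt(p * (1 - p) / n_alleles)
        assert abs(af_hat - p) <= 3 * sd + 1e-12

    def test_sv_catalog_structure(self):
        spec = _small_spec()
        _, cat = simulate_genotypes(spec, 6)
        svs = cat[cat["is_sv"]]
        assert (svs["svlen"].abs() >= 50).all()
        ins = svs[svs["svtype"] == "INS"]
        assert (ins["end"] == ins["start"]).all()
        assert all(len(s) == l for s, l in zip(ins["seq"], ins["svlen"]))
        dels = svs[svs["svtype"] == "DEL"]
        assert (dels["svlen"] < 0).all()
        assert (dels["end"] - dels["start"] == dels["svlen"].abs()).all()

    def test_insertion_length_modes_near_alu_and_line(self):
        spec = CohortSpec(name="big", n_samples=5, n_sv=3000, n_snv=0,
                          chrom_length=200_000_000)
        _, cat = simulate_genotypes(spec, 7)
        ins_len = cat.loc[cat["svtype"] == "INS", "svlen"]
        short = ((ins_len > 150) & (ins_len < 600)).mean()
        long = ((ins_len > 3000) & (ins_len < 12000)).mean()
        assert short > 0.5 and long > 0.1


class TestSharedCatalog:
    def test_two_cohorts_share_allele_frequencies(self):
        # the cross-cohort scenario: same variants, same frequency law,
        # independent haplotypes -> strongly concordant carrier freqs
        spec_a = _small_spec(n_samples=150, n_sv=50, n_snv=250)
        gmat_a, cat = simulate_genotypes(spec_a, 31)
        spec_b = _small_spec(name="u", n_samples=100)
        gmat_b, cat_b = simulate_genotypes(spec_b, 31, catalog=cat)
        pd.testing.assert_frame_equal(cat, cat_b)
        fa = (gmat_a.dosages >= 1).mean(axis=1)
        fb = (gmat_b.dosages >= 1).mean(axis=1)
        assert np.corrcoef(fa, fb)[0, 1] > 0.8
        assert gmat_b.n_samples == 100


class TestCallerObservation:
    def test_noiseless_limit_reproduces_truth(self):
        spec = _small_spec()
        gmat, cat = simulate_genotypes(spec, 8)
        model = CallerNoiseModel(
            breakpoint_jitter_sd=0, edit_rate=0, dropout=0, symbolic_prob=0,
            caller="read",
        )
        calls = observe_caller_calls(cat, gmat, {"read": model}, 8)
        svs = cat[cat["is_sv"]]
        for i, (vid, row) in enumerate(svs.iterrows()):
            vi = cat.index.get_loc(vid)
            for j, s in enumerate(gmat.samples):
                d = gmat.dosages[vi, j]
                hits = [
                    r for r in calls["read"][s]
                    if r.provenance[0].endswith(f":{vid}")
                ]
                if d >= 1:
                    assert len(hits) == 1
                    r = hits[0]
                    assert (r.start, r.svtype) == (row["start"], row["svtype"])
                    assert r.svlen == row["svlen"]
                    if r.svtype == "INS":
                        assert r.seq == row["seq"]
                    assert r.genotypes == {s: int(d)}
                else:
                    assert hits == []

    def test_dropout_fraction_within_three_binomial_sd(self):
        spec = CohortSpec(name="d", n_samples=60, n_sv=120, n_snv=0,
                          chrom_length=20_000_000, common_fraction=1.0)
        gmat, cat = simulate_genotypes(spec, 9)
        n_carry = int((gmat.dosages >= 1).sum())
        assert n_carry > 1000
        model = CallerNoiseModel(dropout=0.1, breakpoint_jitter_sd=0,
                                 edit_rate=0, caller="read")
        calls = observe_caller_calls(cat, gmat, {"read": model}, 9)
        n_obs = sum(len(v) for v in calls["read"].values())
        missing_frac = 1 - n_obs / n_carry
        sd = np.sqrt(0.1 * 0.9 / n_carry)
        assert abs(missing_frac - 0.1) <= 3 * sd

    def test_symbolic_probability_one_makes_all_read_dels_unresolved(self):
        spec = _small_spec()
        gmat, cat = simulate_genotypes(spec, 10)
        ref = {"chr1": "A" * spec.chrom_length}
        model = CallerNoiseModel(symbolic_prob=1.0, caller="read")
        calls = observe_caller_calls(cat, gmat, {"read": model}, 10,
                                     reference=ref)
        dels = [
            r for v in calls["read"].values() for r in v if r.svtype == "DEL"
        ]
        assert dels and all(not r.sequence_resolved for r in dels)

    def test_assembly_caller_quality_always_zero(self):
        spec = _small_spec()
        gmat, cat = simulate_genotypes(spec, 11)
        calls = observe_caller_calls(cat, gmat, default_noise_models(), 11)
        asm = [r for v in calls["assembly"].values() for r in v]
        rd = [r for v in calls["read"].values() for r in v]
        assert asm and all(r.quality == 0.0 for r in asm)
        assert rd and all(r.quality > 0 for r in rd)


class TestCoverage:
    def test_zero_gap_rate_full_coverage(self):
        spec = _small_spec(n_samples=3)
        cov = simulate_coverage_beds(spec, 0.0, 12)
        for haps in cov.values():
            for h in (1, 2):
                assert haps[h][spec.chrom] == [(0, spec.chrom_length)]

    def test_gap_rate_one_empty_beds(self):
        spec = _small_spec(n_samples=3)
        cov = simulate_coverage_beds(spec, 1.0, 13)
        for haps in cov.values():
            for h in (1, 2):
                assert haps[h][spec.chrom] == []

    def test_uncovered_fraction_matches_gap_rate(self):
        spec = _small_spec(n_samples=20, chrom_length=5_000_000)
        gap = 0.2
        cov = simulate_coverage_beds(spec, gap, 14, tile=10_000)
        total = 0
        covered = 0
        for haps in cov.values():
            for h in (1, 2):
                total += spec.chrom_length
                covered += sum(e - s for s, e in haps[h][spec.chrom])
        uncovered = 1 - covered / total
        n_tiles = 20 * 2 * (spec.chrom_length // 10_000)
        sd = np.sqrt(gap * (1 - gap) / n_tiles)
        assert abs(uncovered - gap) <= 4 * sd


class TestExpression:
    def _setup(self, seed=15, n=200):
        spec = _small_spec(n_samples=n, common_fraction=1.0)
        gmat, cat = simulate_genotypes(spec, seed)
        cov = simulate_covariates(spec, seed)
        meta, truth = plant_expression_truth(cat, spec, seed, n_genes=10,
                                             n_qtl=3)
        return spec, gmat, cat, cov, meta, truth

    def test_null_effect_uncorrelated(self):
        spec, gmat, cat, cov, meta, _ = self._setup()
        truth = TruthTable(effects=[])
        Y = simulate_expression(gmat, meta, truth, cov, 16)
        g = gmat.dosages[0].astype(float)
        if g.std() > 0:
            r = np.corrcoef(g, Y.iloc[0])[0, 1]
            assert abs(r) < 0.25

    def test_noiseless_effect_recovered_exactly(self):
        spec, gmat, cat, cov, meta, _ = self._setup()
        sds = gmat.dosages.std(axis=1)
        vid = gmat.variants.index[int(np.argmax(sds))]
        truth = TruthTable(effects=[
            PlantedEffect(meta.index[0], vid, beta=1.0, sigma=0.0,
                          kind="expression")
        ])
        Y = simulate_expression(gmat, meta, truth, cov, 17, sigma=0.0)
        g = gmat.dosages[gmat.variants.index.get_loc(vid)].astype(float)
        beta_hat = np.polyfit(g, Y.loc[meta.index[0]].to_numpy(), 1)[0]
        assert beta_hat == pytest.approx(1.0, abs=1e-10)

    def test_planted_beta_recovered_within_three_se(self):
        spec, gmat, cat, cov, meta, _ = self._setup()
        sds = gmat.dosages.std(axis=1)
        vid = gmat.variants.index[int(np.argmax(sds))]
        truth = TruthTable(effects=[
            PlantedEffect(meta.index[0], vid, beta=0.5, sigma=1.0,
                          kind="expression")
        ])
        Y = simulate_expression(gmat, meta, truth, cov, 18)
        g = gmat.dosages[gmat.variants.index.get_loc(vid)].astype(float)
        y = Y.loc[meta.index[0]].to_numpy()
        n = g.size
        b = np.cov(g, y)[0, 1] / g.var(ddof=1)
        resid = y - y.mean() - b * (g - g.mean())
        se = np.sqrt(resid.var(ddof=2) / (g.var(ddof=1) * (n - 1)))
        assert abs(b - 0.5) < 3 * se

    def test_truth_table_validates_variant_ids(self):
        spec, gmat, cat, cov, meta, _ = self._setup()
        truth = TruthTable(effects=[
            PlantedEffect("g", "not_a_variant", 1.0, 1.0, "expression")
        ])
        with pytest.raises(ValueError):
            simulate_expression(gmat, meta, truth, cov, 19)


class TestMethylation:
    def _setup(self, seed=20, n=100):
        from svqtl.methylation import build_adaptive_windows

        spec = _small_spec(n_samples=n)
        gmat, cat = simulate_genotypes(spec, seed)
        cpgs = simulate_cpg_positions(spec, seed, n_clusters=10)
        windows = build_adaptive_windows(cpgs)
        cov = simulate_covariates(spec, seed)
        return spec, gmat, cpgs, windows, cov

    def test_fractions_always_in_unit_interval(self):
        spec, gmat, cpgs, windows, cov = self._setup()
        truth = TruthTable(age_slopes={windows[0].name: 0.05})
        tracks = simulate_methylation(gmat, cpgs, windows, truth, cov["age"], 21)
        for t in tracks.values():
            assert ((t["fraction"] >= 0) & (t["fraction"] <= 1)).all()

    def test_null_window_uncorrelated_with_age(self):
        spec, gmat, cpgs, windows, cov = self._setup()
        truth = TruthTable()
        tracks = simulate_methylation(gmat, cpgs, windows, truth, cov["age"], 22)
        w = windows[0]
        means = []
        for s in gmat.samples:
            t = tracks[s]
            sel = (t["pos"] >= w.interval.start) & (t["pos"] < w.interval.end)
            means.append(t.loc[sel, "fraction"].mean())
        r = np.corrcoef(cov["age"], means)[0, 1]
        assert abs(r) < 0.3

    def test_planted_age_slope_recovered_on_fraction_scale(self):
        # logit-scale slope chosen to move window means by ~0.1 / 50 years
        spec, gmat, cpgs, windows, cov = self._setup(n=150)
        w = windows[0]
        truth = TruthTable(age_slopes={w.name: 0.012})
        tracks = simulate_methylation(
            gmat, cpgs, windows, truth, cov["age"], 23, noise_sd_logit=0.05
        )
        means = []
        for s in gmat.samples:
            t = tracks[s]
            sel = (t["pos"] >= w.interval.start) & (t["pos"] < w.interval.end)
            means.append(t.loc[sel, "fraction"].mean())
        slope = np.polyfit(cov["age"], means, 1)[0]
        assert slope > 0.0005  # clearly positive trend on the fraction scale

    def test_deterministic_given_seed(self):
        spec, gmat, cpgs, windows, cov = self._setup()
        truth = TruthTable(age_slopes={windows[0].name: 0.02})
        t1 = simulate_methylation(gmat, cpgs, windows, truth, cov["age"], 24)
        t2 = simulate_methylation(gmat, cpgs, windows, truth, cov["age"], 24)
        for s in gmat.samples:
            pd.testing.assert_frame_equal(t1[s], t2[s])


class TestBundleConsistency:
    def test_truth_ids_exist_and_samples_agree(self, tiny_cohort):
        c = tiny_cohort
        for e in c.truth.effects:
            assert e.variant_id in c.gmat.variants.index
        assert list(c.expression.columns) == c.gmat.samples
        assert list(c.covariates.index) == c.gmat.samples
        assert sorted(c.methylation) == sorted(c.gmat.samples)
        for caller, per_sample in c.caller_calls.items():
            assert sorted(per_sample) == sorted(c.gmat.samples)
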