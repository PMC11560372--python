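"""Unit and property tests for SNP filtering and diversity statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import subgenomics as sg
from subgenomics.popgen import MISSING, ValidationError, _maf

from conftest import TOY_SAMPLES, random_matrix, toy_vcf_records, vcf_text


# ---------------------------------------------------------------------------
# read_vcf
# ---------------------------------------------------------------------------


class TestReadVcf:
    def test_basic_code_mapping(self, tmp_path):
        recs = [
            "chr1\t10\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1",
            "chr1\t20\t.\tC\tG\t.\tPASS\t.\tGT\t1/1\t./.",
            "chr1\t30\t.\tG\tA\t.\tPASS\t.\tGT\t0|1\t./1",
        ]
        p = tmp_path / "t.vcf"
        p.write_text(vcf_text(recs, ["a", "b"]))
        gm = sg.read_vcf(p)
        assert gm.samples == ["a", "b"]
        expect = np.array([[0, 1], [2, MISSING], [1, MISSING]], dtype=np.int8)
        np.testing.assert_array_equal(gm.calls, expect)
        assert gm.sites["pos"].tolist() == [10, 20, 30]

    def test_empty_body(self, tmp_path):
        p = tmp_path / "empty.vcf"
        p.write_text(vcf_text([], ["a", "b"]))
        gm = sg.read_vcf(p)
        assert gm.n_sites == 0 and gm.n_samples == 2

    def test_duplicate_position_rejected(self, tmp_path):
        recs = [
            "chr1\t10\t.\tA\tT\t.\tPASS\t.\tGT\t0/0",
            "chr1\t10\t.\tA\tG\t.\tPASS\t.\tGT\t0/0",
        ]
        p = tmp_path / "dup.vcf"
        p.write_text(vcf_text(recs, ["a"]))
        with pytest.raises(sg.VcfParseError, match="duplicate"):
            sg.read_vcf(p)

    def test_simulated_vcf_round_trips(self, tmp_path):
        cfg = sg.GenotypeSimConfig(
            n_pops=2, pop_sizes=(4, 4), fst=(0.1, 0.2), n_sites=150,
            missing_rate=0.05,
        )
        gm, _, _, _ = sg.simulate_structured_genotypes(cfg, seed=7, out_dir=tmp_path)
        gm2 = sg.read_vcf(tmp_path / "genotypes.vcf")
        assert gm2.samples == gm.samples
        assert gm2.site_key() == gm.site_key()
        np.testing.assert_array_equal(gm2.calls, gm.calls)
        np.testing.assert_array_equal(gm2.depths, gm.depths)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


class TestDepthFilter:
    def _gm(self, depths):
        depths = np.asarray(depths)
        n_sites = depths.shape[0]
        sites = pd.DataFrame(
            {"chrom": ["chr1"] * n_sites,
             "pos": np.arange(1, n_sites + 1),
             "ref": ["A"] * n_sites, "alts": [("T",)] * n_sites}
        )
        calls = np.zeros_like(depths, dtype=np.int8)
        return sg.GenotypeMatrix(
            sites=sites, samples=[f"s{j}" for j in range(depths.shape[1])],
            calls=calls, depths=depths,
        )

    def test_uniform_depth_removes_nothing(self):
        gm = self._gm(np.full((20, 4), 30))
        assert sg.filter_depth_outliers(gm).n_sites == 20

    def test_single_outlier_site_removed(self):
        # 99 sites at depth 10 plus one at 2000: overall mean 29.9, so only
        # the 2000x site exceeds 10x the mean
        depths = np.full((100, 1), 10)
        depths[42, 0] = 2000
        gm = self._gm(depths)
        out = sg.filter_depth_outliers(gm)
        assert out.n_sites == 99
        assert 43 not in out.sites["pos"].tolist()  # pos is 1-based

    def test_single_site_never_removed(self):
        gm = self._gm(np.full((1, 3), 500))
        assert sg.filter_depth_outliers(gm).n_sites == 1

    def test_requires_depths(self, rng):
        gm = random_matrix(rng, n_sites=5)
        with pytest.raises(ValidationError, match="skip"):
            sg.filter_depth_outliers(gm)

    def test_input_unchanged(self):
        depths = np.full((10, 2), 10)
        depths[0] = 5000
        gm = self._gm(depths)
        before = gm.calls.copy()
        sg.filter_depth_outliers(gm)
        np.testing.assert_array_equal(gm.calls, before)
        assert gm.n_sites == 10


class TestSiteFilters:
    def _gm_one_site(self, calls, alts=("T",)):
        sites = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [100], "ref": ["A"], "alts": [alts]}
        )
        calls = np.asarray([calls], dtype=np.int8)
        return sg.GenotypeMatrix(
            sites=sites, samples=[f"s{j}" for j in range(calls.shape[1])], calls=calls
        )

    def test_multiallelic_removed(self):
        gm = self._gm_one_site([0] * 10, alts=("T", "G"))
        assert sg.filter_sites(gm).n_sites == 0

    def test_het_boundary_strict(self):
        # 5 het / 5 hom-ref: het fraction exactly 0.5, "<0.5" is strict
        gm = self._gm_one_site([1] * 5 + [0] * 5)
        assert sg.filter_sites(gm).n_sites == 0
        gm = self._gm_one_site([1] * 4 + [0] * 6)
        assert sg.filter_sites(gm).n_sites == 1

    def test_missing_boundary_strict(self):
        gm = self._gm_one_site([MISSING] + [0] * 9)
        assert sg.filter_sites(gm).n_sites == 0
        gm = self._gm_one_site([MISSING] + [0] * 19)
        assert sg.filter_sites(gm).n_sites == 1


class TestMafFilter:
    def test_rare_site_kept_by_drop_above(self, rng):
        gm = random_matrix(rng, n_sites=1, n_samples=10, missing_rate=0)
        gm.calls[0] = np.array([1] + [0] * 9, dtype=np.int8)  # MAF 0.05
        assert sg.maf_filter(gm, 0.1, "drop_above").n_sites == 1
        assert sg.maf_filter(gm, 0.1, "drop_below").n_sites == 0

    def test_boundary_maf_exactly_threshold_retained(self, rng):
        gm = random_matrix(rng, n_sites=1, n_samples=10, missing_rate=0)
        gm.calls[0] = np.array([2, 0, 0, 0, 0, 0, 0, 0, 0, 0], dtype=np.int8)  # MAF 0.1
        assert sg.maf_filter(gm, 0.1, "drop_above").n_sites == 1
        assert sg.maf_filter(gm, 0.1, "drop_below").n_sites == 1

    def test_brute_force_allele_count_oracle(self, rng):
        gm = random_matrix(rng, n_sites=60, n_samples=15)
        for mode in ("drop_above", "drop_below"):
            out = sg.maf_filter(gm, 0.2, mode)
            survivors = set(out.site_key())
            for i in range(gm.n_sites):
                alt = ref = 0
                for c in gm.calls[i]:
                    if c == MISSING:
                        continue
                    alt += int(c)
                    ref += 2 - int(c)
                if alt + ref == 0:
                    expect_keep = True
                else:
                    maf = min(alt, ref) / (alt + ref)
                    expect_keep = not (
                        maf > 0.2 if mode == "drop_above" else maf < 0.2
                    )
                key = (gm.sites["chrom"][i], gm.sites["pos"][i])
                assert (key in survivors) == expect_keep

    def test_rejects_multiallelic(self, rng):
        gm = random_matrix(rng, n_sites=2)
        gm.sites.at[0, "alts"] = ("T", "G")
        with pytest.raises(ValidationError, match="filter_sites"):
            sg.maf_filter(gm)


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------


class TestLdR2:
    def test_identical_vectors(self):
        assert sg.ld_r2([0, 1, 2, 1], [0, 1, 2, 1]) == pytest.approx(1.0)

    def test_sign_invariant(self):
        assert sg.ld_r2([0, 0, 2, 2], [2, 2, 0, 0]) == pytest.approx(1.0)

    def test_constant_vector_flagged_zero(self):
        r2, defined = sg.ld_r2([1, 1, 1, 1], [0, 1, 2, 0], return_defined=True)
        assert r2 == 0.0 and not defined

    def test_matches_hand_coded_pearson(self, rng):
        for _ in range(20):
            a = rng.integers(0, 3, 25).astype(float)
            b = rng.integers(0, 3, 25).astype(float)
            a[rng.random(25) < 0.1] = np.nan
            b[rng.random(25) < 0.1] = np.nan
            ok = ~(np.isnan(a) | np.isnan(b))
            x, y = a[ok], b[ok]
            if len(x) < 2 or np.all(x == x[0]) or np.all(y == y[0]):
                continue
            n = len(x)
            num = n * (x * y).sum() - x.sum() * y.sum()
            den = math.sqrt(n * (x * x).sum() - x.sum() ** 2) * math.sqrt(
                n * (y * y).sum() - y.sum() ** 2
            )
            assert sg.ld_r2(a, b) == pytest.approx((num / den) ** 2, abs=1e-12)


class TestLdPrune:
    def test_adjacent_duplicates_keep_one(self, rng):
        gm = random_matrix(rng, n_sites=2, n_samples=10, missing_rate=0)
        gm.calls[1] = gm.calls[0]
        if len(set(gm.calls[0].tolist())) == 1:  # avoid constant vector
            gm.calls[0, 0] = 2
            gm.calls[1, 0] = 2
        out = sg.ld_prune(gm)
        assert out.n_sites == 1
        assert out.sites["pos"][0] == gm.sites["pos"][0]  # later site dropped

    def test_independent_sites_all_retained(self):
        rng = np.random.default_rng(11)
        n_sites, n_samples = 40, 400
        p = rng.uniform(0.2, 0.8, n_sites)
        calls = rng.binomial(2, p[:, None], (n_sites, n_samples)).astype(np.int8)
        sites = pd.DataFrame(
            {"chrom": ["chr1"] * n_sites, "pos": np.arange(1, n_sites + 1) * 10,
             "ref": ["A"] * n_sites, "alts": [("T",)] * n_sites}
        )
        gm = sg.GenotypeMatrix(sites=sites, samples=[f"s{j}" for j in range(n_samples)],
                               calls=calls)
        assert sg.ld_prune(gm, r2_max=0.4).n_sites == n_sites

    def test_postcondition_no_window_pair_above_threshold(self, rng):
        # correlated blocks force pruning; verify by exhaustive window scan
        base = rng.integers(0, 3, size=(8, 30)).astype(np.int8)
        calls = np.repeat(base, 4, axis=0)  # blocks of 4 near-identical sites
        flip = rng.random(calls.shape) < 0.05
        calls = np.where(flip, rng.integers(0, 3, calls.shape), calls).astype(np.int8)
        sites = pd.DataFrame(
            {"chrom": ["chr1"] * 32, "pos": np.arange(1, 33) * 7,
             "ref": ["A"] * 32, "alts": [("T",)] * 32}
        )
        gm = sg.GenotypeMatrix(sites=sites, samples=[f"s{j}" for j in range(30)],
                               calls=calls)
        out = sg.ld_prune(gm, r2_max=0.4, window_sites=10, step_sites=2)
        dos = out.dosages()
        n = out.n_sites
        for start in range(0, n, 2):
            win = range(start, min(start + 10, n))
            for i in win:
                for j in win:
                    if i < j:
                        assert sg.ld_r2(dos[i], dos[j]) <= 0.4 + 1e-12

    def test_window_too_small_rejected(self, rng):
        with pytest.raises(ValidationError):
            sg.ld_prune(random_matrix(rng), window_sites=1)


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------


def brute_force_site_pi(calls):
    """Mean pairwise difference over all haplotype pairs (the definition)."""
    haps = []
    for c in calls:
        if c == MISSING:
            continue
        haps.extend({0: [0, 0], 1: [0, 1], 2: [1, 1]}[c])
    n = len(haps)
    if n < 2:
        return None
    diff = sum(
        haps[i] != haps[j] for i in range(n) for j in range(i + 1, n)
    )
    return diff / (n * (n - 1) // 2)


class TestSitePi:
    def test_forced_by_formula(self):
        # alleles A,A,A,T: 3·1 differing pairs out of C(4,2)=6
        assert sg.site_pi([0, 1]) == pytest.approx(0.5)

    def test_monomorphic_is_zero(self):
        assert sg.site_pi([0, 0, 0]) == 0.0

    def test_all_missing_skipped(self):
        assert sg.site_pi([MISSING, MISSING]) is None

    @given(st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=1, max_size=20))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_equals_brute_force_pairwise_mean(self, calls):
        assert sg.site_pi(calls) == brute_force_site_pi(calls)


class TestWindowedPi:
    def test_single_site_single_window(self, rng):
        gm = random_matrix(rng, n_sites=1, n_samples=2, missing_rate=0)
        gm.calls[0] = np.array([0, 1], dtype=np.int8)  # site pi = 0.5
        gm.sites.at[0, "pos"] = 500
        dr = sg.windowed_pi(gm, 1000, {"chr1": 1000})
        assert len(dr.windows) == 1
        assert dr.windows["pi_per_bp"][0] == pytest.approx(5e-4)

    def test_no_variants_all_zero(self, rng):
        gm = random_matrix(rng, n_sites=10, n_samples=5, missing_rate=0)
        gm.calls[:] = 0
        dr = sg.windowed_pi(gm, 5000, {"chr1": 100_000})
        assert (dr.windows["pi_per_bp"] == 0).all()
        assert len(dr.windows) == 20

    def test_trailing_partial_window_span(self, rng):
        gm = random_matrix(rng, n_sites=3, n_samples=4, missing_rate=0)
        dr = sg.windowed_pi(gm, 30_000, {"chr1": 70_000})
        last = dr.windows.iloc[-1]
        assert last["start"] == 60_001 and last["end"] == 70_000

    def test_brute_force_window_sums(self, rng):
        gm = random_matrix(rng, n_sites=50, n_samples=10)
        dr = sg.windowed_pi(gm, 10_000, {"chr1": 100_000})
        for _, w in dr.windows.iterrows():
            total = 0.0
            for i in range(gm.n_sites):
                if w["start"] <= gm.sites["pos"][i] <= w["end"]:
                    p = sg.site_pi(gm.calls[i])
                    total += 0.0 if p is None else p
            assert w["sum_site_pi"] == pytest.approx(total)


class TestAggregatePi:
    def _dr(self, rows):
        return sg.DiversityResult(windows=pd.DataFrame(
            rows, columns=["chrom", "start", "end", "n_sites", "sum_site_pi", "pi_per_bp"]
        ))

    def test_constant_windows(self, simple_sgmap):
        rows = [(c, 1, 1000, 1, 1.0, 0.001) for c in ("chr1", "chr2", "chr3")]
        agg = sg.aggregate_pi(self._dr(rows), simple_sgmap)
        for sg_label in ("SG1", "SG2", "SG3", "genome"):
            assert agg[sg_label] == pytest.approx(0.001)

    def test_equal_length_windows_average(self, simple_sgmap):
        rows = [("chr1", 1, 1000, 0, 0.0, 0.0), ("chr1", 1001, 2000, 5, 2.0, 0.002)]
        agg = sg.aggregate_pi(self._dr(rows), simple_sgmap)
        assert agg["SG1"] == pytest.approx(0.001)

    def test_empty_subgenome_is_nan_not_zero(self, simple_sgmap):
        rows = [("chr1", 1, 1000, 1, 1.0, 0.001)]
        agg = sg.aggregate_pi(self._dr(rows), simple_sgmap)
        assert math.isnan(agg["SG2"])

    def test_unmapped_chromosome_rejected(self, simple_sgmap):
        rows = [("chrX", 1, 1000, 1, 1.0, 0.001)]
        with pytest.raises(ValidationError):
            sg.aggregate_pi(self._dr(rows), simple_sgmap)

    def test_genome_value_invariant_to_subgenome_split(self, rng, simple_sgmap):
        gms = [random_matrix(rng, n_sites=40, chrom=c) for c in ("chr1", "chr2", "chr3")]
        sites = pd.concat([g.sites for g in gms], ignore_index=True)
        calls = np.vstack([g.calls for g in gms])
        gm = sg.GenotypeMatrix(sites=sites, samples=gms[0].samples, calls=calls)
        dr = sg.windowed_pi(gm, 10_000, simple_sgmap.lengths)
        agg = sg.aggregate_pi(dr, simple_sgmap)
        w = dr.windows
        span = (w["end"] - w["start"] + 1)
        direct = (w["pi_per_bp"] * span).sum() / span.sum()
        assert agg["genome"] == pytest.approx(direct)
        # recombining subgenome aggregates bp-weighted reproduces the genome value
        bp = {s: 100_000 for s in ("SG1", "SG2", "SG3")}
        recomb = sum(agg[s] * bp[s] for s in bp) / sum(bp.values())
        assert recomb == pytest.approx(agg["genome"])

    def test_subgenome_diversity_scaling_recovered(self):
        cfg = sg.GenotypeSimConfig(
            n_pops=2, pop_sizes=(30, 30), fst=(0.05, 0.05), n_sites=12_000,
            missing_rate=0.0, diversity_scale={"SG1": 1.0, "SG2": 1.0, "SG3": 0.8},
        )
        gm, _, sgmap, _ = sg.simulate_structured_genotypes(cfg, seed=5)
        dr = sg.windowed_pi(gm, 100_000, sgmap.lengths)
        agg = sg.aggregate_pi(dr, sgmap)
        assert agg["SG3"] / agg["SG1"] == pytest.approx(0.8, abs=0.06)


# ---------------------------------------------------------------------------
# heterozygosity
# ---------------------------------------------------------------------------


class TestHeterozygosity:
    def test_basic_fraction(self, rng):
        gm = random_matrix(rng, n_sites=4, n_samples=1, missing_rate=0)
        gm.calls[:, 0] = np.array([1, 0, 2, MISSING], dtype=np.int8)
        het = sg.individual_heterozygosity(gm)
        assert het.table["H_genome"].iloc[0] == pytest.approx(1 / 3)

    def test_all_het_sample(self, rng):
        gm = random_matrix(rng, n_sites=5, n_samples=2, missing_rate=0)
        gm.calls[:, 0] = 1
        het = sg.individual_heterozygosity(gm)
        assert het.table["H_genome"].iloc[0] == 1.0

    def test_all_missing_flagged(self, rng):
        gm = random_matrix(rng, n_sites=5, n_samples=2, missing_rate=0)
        gm.calls[:, 1] = MISSING
        het = sg.individual_heterozygosity(gm)
        assert het.undefined_samples == [gm.samples[1]]

    def test_brute_force_tally_and_subgenome_sum(self, rng, simple_sgmap):
        gms = [random_matrix(rng, n_sites=30, chrom=c) for c in ("chr1", "chr2", "chr3")]
        gm = sg.GenotypeMatrix(
            sites=pd.concat([g.sites for g in gms], ignore_index=True),
            samples=gms[0].samples,
            calls=np.vstack([g.calls for g in gms]),
        )
        het = sg.individual_heterozygosity(gm, simple_sgmap)
        for j, s in enumerate(gm.samples):
            col = gm.calls[:, j]
            nonmiss = (col != MISSING).sum()
            expect = (col == 1).sum() / nonmiss
            assert het.table.loc[s, "H_genome"] == pytest.approx(expect)
        # genome-wide non-missing = sum over subgenomes
        for j, s in enumerate(gm.samples):
            parts = 0
            for sg_label, chroms in (("SG1", "chr1"), ("SG2", "chr2"), ("SG3", "chr3")):
                sel = (gm.sites["chrom"] == chroms).to_numpy()
                parts += (gm.calls[sel, j] != MISSING).sum()
            assert parts == het.table.loc[s, "n_nonmissing"]

    def test_invariant_to_sample_relabeling_and_site_order(self, rng):
        gm = random_matrix(rng, n_sites=40, n_samples=8)
        het1 = sg.individual_heterozygosity(gm).table["H_genome"]
        perm = rng.permutation(gm.n_sites)
        sites = gm.sites.iloc[perm].sort_values("pos").reset_index(drop=True)
        order = gm.sites.index[perm][np.argsort(gm.sites["pos"].iloc[perm].to_numpy())]
        gm2 = sg.GenotypeMatrix(sites=sites, samples=gm.samples, calls=gm.calls[order])
        het2 = sg.individual_heterozygosity(gm2).table["H_genome"]
        np.testing.assert_allclose(het1.to_numpy(), het2.to_numpy())


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------


def _two_pop_gm(calls_a, calls_b):
    calls = np.hstack([calls_a, calls_b]).astype(np.int8)
    n_sites = calls.shape[0]
    sites = pd.DataFrame(
        {"chrom": ["chr1"] * n_sites, "pos": np.arange(1, n_sites + 1),
         "ref": ["A"] * n_sites, "alts": [("T",)] * n_sites}
    )
    samples = [f"a{j}" for j in range(calls_a.shape[1])] + [
        f"b{j}" for j in range(calls_b.shape[1])
    ]
    pops = {s: ("A" if s.startswith("a") else "B") for s in samples}
    return sg.GenotypeMatrix(sites=sites, samples=samples, calls=calls), pops


class TestWcFst:
    def test_complete_fixation_is_one(self):
        gm, pops = _two_pop_gm(np.zeros((50, 10)), np.full((50, 10), 2))
        res = sg.wc_fst(gm, pops, ("A", "B"))
        assert res.weighted_fst == pytest.approx(1.0)

    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(42)
        p = rng.uniform(0.1, 0.9, 2000)
        pooled = rng.binomial(2, p[:, None], (2000, 100)).astype(np.int8)
        gm, pops = _two_pop_gm(pooled[:, :50], pooled[:, 50:])
        res = sg.wc_fst(gm, pops, ("A", "B"))
        assert abs(res.weighted_fst) <= 0.02

    def test_pooled_then_split_many_seeds(self):
        # under the null the weighted estimator stays within ±0.02
        for seed in range(20):
            rng = np.random.default_rng(seed)
            p = rng.uniform(0.05, 0.95, 2000)
            pooled = rng.binomial(2, p[:, None], (2000, 100)).astype(np.int8)
            gm, pops = _two_pop_gm(pooled[:, :50], pooled[:, 50:])
            assert abs(sg.wc_fst(gm, pops, ("A", "B")).weighted_fst) <= 0.02

    def test_balding_nichols_parameter_recovery(self):
        cfg = sg.GenotypeSimConfig(
            n_pops=2, pop_sizes=(50, 50), fst=(0.1, 0.1), n_sites=5000,
            missing_rate=0.0, diversity_scale={"SG1": 1, "SG2": 1, "SG3": 1},
        )
        gm, popmap, _, _ = sg.simulate_structured_genotypes(cfg, seed=1)
        res = sg.wc_fst(gm, popmap, ("pop1", "pop2"))
        assert res.weighted_fst == pytest.approx(0.1, abs=0.02)

    def test_unknown_population_rejected(self, rng):
        gm = random_matrix(rng, n_sites=5, n_samples=4)
        pops = {s: "A" for s in gm.samples}
        with pytest.raises(ValidationError, match="unknown population"):
            sg.wc_fst(gm, pops, ("A", "Z"))

    def test_weighted_fst_at_most_one(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            gm, pops = _two_pop_gm(
                r.integers(0, 3, (200, 8)), r.integers(0, 3, (200, 8))
            )
            assert sg.wc_fst(gm, pops, ("A", "B")).weighted_fst <= 1.0


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


class TestGenotypePca:
    def test_two_duplicated_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(0)
        proto = rng.integers(0, 3, (100, 2)).astype(np.int8)
        while np.array_equal(proto[:, 0], proto[:, 1]):
            proto = rng.integers(0, 3, (100, 2)).astype(np.int8)
        calls = np.repeat(proto, 5, axis=1)  # 5 copies of each prototype
        sites = pd.DataFrame(
            {"chrom": ["chr1"] * 100, "pos": np.arange(1, 101),
             "ref": ["A"] * 100, "alts": [("T",)] * 100}
        )
        gm = sg.GenotypeMatrix(sites=sites, samples=[f"s{j}" for j in range(10)],
                               calls=calls)
        coords, _, _ = sg.genotype_pca(gm, 2)
        c1, c2 = coords[:5, 0], coords[5:, 0]
        assert np.ptp(c1) == pytest.approx(0, abs=1e-8)
        assert np.ptp(c2) == pytest.approx(0, abs=1e-8)
        assert abs(c1[0] - c2[0]) > 1e-6

    def test_three_population_recovery_by_kmeans(self):
        from scipy.optimize import linear_sum_assignment
        from sklearn.cluster import KMeans

        cfg = sg.GenotypeSimConfig(
            n_pops=3, pop_sizes=(30, 30, 30), fst=(0.15, 0.15, 0.15),
            n_sites=2000, missing_rate=0.0,
            diversity_scale={"SG1": 1, "SG2": 1, "SG3": 1},
        )
        gm, popmap, _, _ = sg.simulate_structured_genotypes(cfg, seed=2)
        coords, _, _ = sg.genotype_pca(gm, 2)
        labels = KMeans(n_clusters=3, n_init=10, random_state=0).fit_predict(coords)
        true = np.array([int(popmap[s][3]) - 1 for s in gm.samples])
        conf = np.zeros((3, 3), dtype=int)
        for t, l in zip(true, labels):
            conf[t, l] += 1
        row, col = linear_sum_assignment(-conf)
        assert conf[row, col].sum() / len(true) > 0.9

    def test_axes_orthonormal(self, rng):
        gm = random_matrix(rng, n_sites=50, n_samples=12)
        _, _, comps = sg.genotype_pca(gm, 3)
        np.testing.assert_allclose(comps @ comps.T, np.eye(3), atol=1e-8)

    def test_too_many_components_rejected(self, rng):
        gm = random_matrix(rng, n_sites=50, n_samples=5)
        with pytest.raises(ValidationError):
            sg.genotype_pca(gm, 6)


# ---------------------------------------------------------------------------
# cascade properties
# ---------------------------------------------------------------------------


class TestCascade:
    def test_idempotent(self, rng):
        gm = random_matrix(rng, n_sites=80, n_samples=20)
        once, _ = sg.run_filter_cascade(gm, maf_mode="drop_below")
        twice, _ = sg.run_filter_cascade(once, maf_mode="drop_below")
        assert once.site_key() == twice.site_key()

    def test_survivor_log_non_increasing(self, rng):
        gm = random_matrix(rng, n_sites=60, n_samples=15)
        _, log = sg.run_filter_cascade(gm)
        vals = list(log.values())
        assert all(a >= b for a, b in zip(vals, vals[1:]))
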