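import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dnsatlas.core import DNSTrack
from dnsatlas.genic import (categorize_triplets, expression_dns_correlation,
                            genic_partition_scores, intergenic_partition_scores,
                            metagene, region_abcd, triplet_bias_tests)
from dnsatlas.genome import GenomeAssembly, GenomicInterval, GeneModel


def mk_gene(gid, chrom, s, e, strand="+", cds_off=0):
    return GeneModel(gid, GenomicInterval(chrom, s, e, strand),
                     s + cds_off, e - cds_off)


def const_track(asm, value=0.0):
    return DNSTrack(asm, 10, data={c: np.full(-(-asm.length(c) // 10), value)
                                   for c in asm})


def mwu_exact_oracle(x, y):
    """Two-sided Mann-Whitney p by full enumeration of group assignments."""
    pooled = list(x) + list(y)
    n = len(x)

    def u_stat(xs, ys):
        return sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)

    u_obs = u_stat(x, y)
    mu = len(x) * len(y) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(xs, ys) - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return count / total


def kw_h_oracle(groups):
    """Kruskal-Wallis H with tie correction, from first principles."""
    pooled = np.concatenate(groups)
    order = stats.rankdata(pooled)
    n = pooled.size
    start = 0
    h = 0.0
    for g in groups:
        r = order[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    return h / tie


class TestGenicPartitions:
    def test_constant_track_all_partitions_equal(self):
        asm = GenomeAssembly([("1A", 100_000)])
        genes = [mk_gene("g", "1A", 40_000, 50_000, "+", 500)]
        dns = const_track(asm, 2.5)
        df = genic_partition_scores(dns, genes, asm)
        for col in ("gene_body", "upstream_500", "upstream_2kb", "downstream_2kb"):
            assert df.loc["g", col] == pytest.approx(2.5)
        inter = intergenic_partition_scores(dns, genes, asm)
        np.testing.assert_allclose(inter["mean_dns"], 2.5)

    def test_plus_strand_upstream_window(self):
        asm = GenomeAssembly([("1A", 100_000)])
        genes = [mk_gene("g", "1A", 5_000, 10_000, "+")]  # cds_start 5000
        data = np.zeros(10_000)
        data[450:500] = 1.0  # [4500, 5000)
        dns = DNSTrack(asm, 10, data={"1A": data})
        df = genic_partition_scores(dns, genes, asm)
        assert df.loc["g", "upstream_500"] == pytest.approx(1.0)

    def test_minus_strand_upstream_window(self):
        asm = GenomeAssembly([("1A", 100_000)])
        genes = [mk_gene("g", "1A", 1_000, 5_000, "-")]  # cds_end 5000
        data = np.zeros(10_000)
        data[500:550] = 1.0  # [5000, 5500)
        dns = DNSTrack(asm, 10, data={"1A": data})
        df = genic_partition_scores(dns, genes, asm)
        assert df.loc["g", "upstream_500"] == pytest.approx(1.0)

    def test_truncated_window_flagged(self):
        asm = GenomeAssembly([("1A", 100_000)])
        genes = [mk_gene("g", "1A", 500, 3_000, "+")]
        df = genic_partition_scores(const_track(asm), genes, asm)
        assert bool(df.loc["g", "truncated"])

    def test_intergenic_blocks_are_complement_of_envelopes(self):
        asm = GenomeAssembly([("1A", 100_000)])
        genes = [mk_gene("g1", "1A", 10_000, 14_000),
                 mk_gene("g2", "1A", 50_000, 56_000)]
        inter = intergenic_partition_scores(const_track(asm), genes, asm)
        spans = list(zip(inter["start"], inter["end"]))
        assert spans == [(0, 8_000), (16_000, 48_000), (58_000, 100_000)]


class TestMetagene:
    def test_flat_track_flat_profile(self):
        asm = GenomeAssembly([("1A", 100_000)])
        genes = [mk_gene("g", "1A", 40_000, 50_000)]
        prof = metagene(const_track(asm, 0.7), genes)
        np.testing.assert_allclose(prof["mean_dns"], 0.7)
        assert len(prof) == 200

    def test_impulse_210bp_upstream(self):
        asm = GenomeAssembly([("1A", 100_000)])
        genes = [mk_gene("g", "1A", 5_000, 10_000, "+")]
        data = np.zeros(10_000)
        data[(5_000 - 210) // 10] = 1.0
        dns = DNSTrack(asm, 10, data={"1A": data})
        prof = metagene(dns, genes)
        assert prof["mean_dns"].idxmax() == -210

    def test_mirror_reflection_identity(self, rng):
        L = 100_000
        asm = GenomeAssembly([("1A", L)])
        vals = rng.normal(size=L // 10)
        genes = [mk_gene("g1", "1A", 20_000, 26_000, "+"),
                 mk_gene("g2", "1A", 60_000, 64_000, "-")]
        prof = metagene(DNSTrack(asm, 10, data={"1A": vals}), genes)
        rgenes = [GeneModel(g.gene_id,
                            GenomicInterval("1A", L - g.interval.end,
                                            L - g.interval.start,
                                            "+" if g.strand == "-" else "-"),
                            L - g.cds_end, L - g.cds_start) for g in genes]
        rprof = metagene(DNSTrack(asm, 10, data={"1A": vals[::-1].copy()}), rgenes)
        np.testing.assert_allclose(rprof["mean_dns"], prof["mean_dns"])

    def test_no_genes_rejected(self):
        asm = GenomeAssembly([("1A", 100_000)])
        with pytest.raises(ValueError):
            metagene(const_track(asm), [])


class TestRegionABCD:
    def test_windows_strand_oriented(self):
        asm = GenomeAssembly([("1A", 100_000)])
        g = mk_gene("g", "1A", 50_000, 56_000, "+")  # cds_start 50_000
        data = np.zeros(10_000)
        data[4_900:4_950] = 1.0  # region b = [49_500, 50_000) -> bins 4950..4999
        data[4_950:5_000] = 2.0
        dns = DNSTrack(asm, 10, data={"1A": data})
        df = region_abcd(dns, [g], asm)
        assert df.loc["g", "b"] == pytest.approx(2.0)
        assert df.loc["g", "a"] == pytest.approx(1.0)
        assert df.loc["g", "c"] == pytest.approx(0.0)

    def test_edge_genes_excluded(self):
        asm = GenomeAssembly([("1A", 100_000)])
        g = mk_gene("g", "1A", 200, 4_000, "+")  # -1 kb window off-chromosome
        df = region_abcd(const_track(asm), [g], asm)
        assert "g" not in df.index


class TestExpressionCorrelation:
    def test_monotone_construction_positive(self, rng):
        scores = pd.Series(rng.normal(0, 1, 300),
                           index=[f"g{i}" for i in range(300)])
        tpm = pd.Series(np.exp(scores.to_numpy() * 2 + rng.normal(0, 0.2, 300)),
                        index=scores.index)
        r, p, n = expression_dns_correlation(scores, tpm)
        assert r > 0.8 and p < 1e-10

    def test_permuted_labels_near_zero(self, rng):
        scores = pd.Series(rng.normal(0, 1, 3000),
                           index=[f"g{i}" for i in range(3000)])
        tpm = pd.Series(np.exp(scores.to_numpy()), index=scores.index)
        perm = pd.Series(rng.permutation(tpm.to_numpy()), index=tpm.index)
        r, _, _ = expression_dns_correlation(scores, perm)
        assert abs(r) < 0.1

    def test_low_expression_filtered(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        tpm = pd.Series([0.05, 5.0, 6.0, 7.0], index=list("abcd"))
        _, _, n = expression_dns_correlation(scores, tpm)
        assert n == 3

    def test_constant_dns_undefined(self):
        scores = pd.Series([1.0] * 10, index=[f"g{i}" for i in range(10)])
        tpm = pd.Series(np.arange(1.0, 11.0), index=scores.index)
        r, _, _ = expression_dns_correlation(scores, tpm)
        assert np.isnan(r)


class TestCategorizeTriplets:
    def trip(self):
        return pd.DataFrame({"gene_A": ["a"], "gene_B": ["b"], "gene_D": ["d"]})

    def test_equal_expression_balanced(self):
        out = categorize_triplets(self.trip(), pd.Series({"a": 10, "b": 10, "d": 10}))
        assert out["category"].tolist() == ["balanced"]

    def test_a_dominant(self):
        out = categorize_triplets(self.trip(), pd.Series({"a": 30, "b": 1, "d": 1}))
        assert out["category"].tolist() == ["A.dominant"]

    def test_a_suppressed(self):
        out = categorize_triplets(self.trip(), pd.Series({"a": 1, "b": 30, "d": 30}))
        assert out["category"].tolist() == ["A.suppressed"]

    def test_low_sum_filtered(self):
        out = categorize_triplets(self.trip(), pd.Series({"a": 0.1, "b": 0.1, "d": 0.1}))
        assert len(out) == 0

    def test_missing_homoeolog_warns_and_skips(self):
        with pytest.warns(UserWarning):
            out = categorize_triplets(self.trip(), pd.Series({"a": 5.0, "b": 5.0}))
        assert len(out) == 0

    def test_subgenome_permutation_equivariance(self, rng):
        trips = pd.DataFrame({"gene_A": [f"a{i}" for i in range(50)],
                              "gene_B": [f"b{i}" for i in range(50)],
                              "gene_D": [f"d{i}" for i in range(50)]})
        tpm = {}
        for i in range(50):
            vals = rng.uniform(0.5, 30, 3)
            tpm[f"a{i}"], tpm[f"b{i}"], tpm[f"d{i}"] = vals
        tpm = pd.Series(tpm)
        orig = categorize_triplets(trips, tpm)["category"]
        swapped_tpm = tpm.copy()
        for i in range(50):
            swapped_tpm[f"a{i}"], swapped_tpm[f"b{i}"] = tpm[f"b{i}"], tpm[f"a{i}"]
        swapped = categorize_triplets(trips, swapped_tpm)["category"]
        remap = {"A.dominant": "B.dominant", "B.dominant": "A.dominant",
                 "A.suppressed": "B.suppressed", "B.suppressed": "A.suppressed"}
        assert swapped.tolist() == [remap.get(c, c) for c in orig]


class TestRankTestOracles:
    @pytest.mark.parametrize("seed", range(4))
    def test_mannwhitney_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 5)
        y = rng.normal(0.5, 1, 4)
        _, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert p == pytest.approx(mwu_exact_oracle(x, y), abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_kruskal_h_matches_first_principles(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.normal(0, 1, 6), rng.normal(0.3, 1, 5), rng.normal(1, 1, 7)]
        h, _ = stats.kruskal(*groups)
        assert h == pytest.approx(kw_h_oracle(groups), abs=1e-10)

    def test_two_group_kruskal_equals_mwu_z_squared(self, rng):
        x, y = rng.normal(0, 1, 12), rng.normal(1, 1, 10)
        h, _ = stats.kruskal(x, y)
        u, _ = stats.mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic")
        n, m = len(x), len(y)
        z = (u - n * m / 2) / np.sqrt(n * m * (n + m + 1) / 12)
        assert h == pytest.approx(z ** 2, abs=1e-10)


class TestTripletBiasTests:
    def _abcd_and_cats(self, rng, shift_b_for_A=0.0, n=60):
        rows = []
        cats = []
        for i in range(n):
            for sub in "ABD":
                base = rng.normal(0, 0.3, 4)
                if sub == "A":
                    base[1] += shift_b_for_A
                rows.append({"gene_id": f"{sub.lower()}{i}",
                             "a": base[0], "b": base[1], "c": base[2], "d": base[3]})
            cats.append({"gene_A": f"a{i}", "gene_B": f"b{i}", "gene_D": f"d{i}",
                         "category": "balanced"})
        abcd = pd.DataFrame(rows).set_index("gene_id")
        return pd.DataFrame(cats), abcd

    def test_null_p_uniform(self):
        rng = np.random.default_rng(10)
        ps = []
        for _ in range(40):
            cats, abcd = self._abcd_and_cats(rng, 0.0, n=30)
            kw = triplet_bias_tests(cats, abcd)
            ps.extend(kw["p"])
        _, ks_p = stats.kstest(ps, "uniform")
        assert ks_p > 0.01

    def test_shifted_genome_detected(self):
        rng = np.random.default_rng(11)
        cats, abcd = self._abcd_and_cats(rng, shift_b_for_A=1.0, n=100)
        kw = triplet_bias_tests(cats, abcd).set_index("region")
        assert kw.loc["b", "p"] < 0.01
        assert kw.loc["a", "p"] > 0.01
        pw = kw.attrs["pairwise"] if "pairwise" in kw.attrs else None

    def test_pairwise_bh_adjustment_present(self):
        rng = np.random.default_rng(12)
        cats, abcd = self._abcd_and_cats(rng, 0.5, n=40)
        kw = triplet_bias_tests(cats, abcd)
        pw = kw.attrs["pairwise"]
        assert {"pair", "p", "p_adj"} <= set(pw.columns)
        assert (pw["p_adj"] >= pw["p"] - 1e-12).all()
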