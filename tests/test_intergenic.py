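import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dnsatlas.core import DNSTrack
from dnsatlas.genome import (GenomeAssembly, GenomicInterval, GeneModel,
                             TEAnnotation)
from dnsatlas.intergenic import (background_dns, decay_profiles,
                                 gene_te_proximity_effect, gypsy_dns_correlation,
                                 intergenic_intervals, promoter_te_comparison,
                                 spacing_class, spacing_class_tests, te_scores)


def mk_gene(gid, chrom, s, e, strand="+"):
    return GeneModel(gid, GenomicInterval(chrom, s, e, strand), s + 100, e - 100)


def const_track(asm, value=0.0, bin_width=10):
    return DNSTrack(asm, bin_width,
                    data={c: np.full(-(-asm.length(c) // bin_width), value)
                          for c in asm})


def spearman_oracle(x, y):
    """rho from first principles on tie-free data."""
    rx = np.argsort(np.argsort(x)) + 1.0
    ry = np.argsort(np.argsort(y)) + 1.0
    n = len(x)
    return 1 - 6 * np.sum((rx - ry) ** 2) / (n * (n ** 2 - 1))


class TestIntervals:
    def test_adjacent_pair(self):
        genes = [mk_gene("g1", "1A", 500, 1000), mk_gene("g2", "1A", 5000, 6000)]
        (iv,) = intergenic_intervals(genes)
        assert (iv.interval.start, iv.interval.end) == (1000, 5000)
        assert iv.spacing_class == "lt10kb"
        assert (iv.left_gene, iv.right_gene) == ("g1", "g2")

    def test_class_boundaries_left_closed(self):
        assert spacing_class(9_999) == "lt10kb"
        assert spacing_class(10_000) == "10to100kb"
        assert spacing_class(100_000) == "100kbto1Mb"
        assert spacing_class(1_000_000) == "gt1Mb"

    def test_overlapping_genes_merge_to_one_block(self):
        genes = [mk_gene("g1", "1A", 0, 1000), mk_gene("g2", "1A", 500, 1500),
                 mk_gene("g3", "1A", 9000, 10_000)]
        (iv,) = intergenic_intervals(genes)
        assert (iv.interval.start, iv.interval.end) == (1500, 9000)

    def test_single_block_chromosome_warns(self):
        with pytest.warns(UserWarning, match="1A"):
            out = intergenic_intervals([mk_gene("g1", "1A", 0, 1000)])
        assert out == []

    def test_length_conservation(self, small_truth):
        """Blocks + intervals + terminal gaps tile each chromosome exactly."""
        from dnsatlas.intergenic import merged_gene_blocks
        ivs = intergenic_intervals(small_truth.genes, small_truth.segments)
        blocks = merged_gene_blocks(small_truth.genes)
        for chrom in small_truth.assembly:
            bl = blocks.get(chrom, [])
            if len(bl) < 2:
                continue
            inter_len = sum(len(x.interval) for x in ivs
                            if x.interval.chrom == chrom)
            block_len = sum(e - s for s, e, _ in bl)
            terminal = bl[0][0] + (small_truth.assembly.length(chrom) - bl[-1][1])
            assert inter_len + block_len + terminal == small_truth.assembly.length(chrom)


class TestDecay:
    def test_window_counts_floor_rule(self):
        asm = GenomeAssembly([("1A", 100_000)])
        genes = [mk_gene("g1", "1A", 0, 1000), mk_gene("g2", "1A", 5000, 6000)]
        ivs = intergenic_intervals(genes)
        series, _ = decay_profiles(const_track(asm), ivs)
        assert all(s["values"].size == 2 for s in series)  # floor(2000/1000)
        assert len(series) == 2  # the two flanks

    def test_flat_track_flat_curves(self):
        asm = GenomeAssembly([("1A", 200_000)])
        genes = [mk_gene("g1", "1A", 0, 1000), mk_gene("g2", "1A", 80_000, 81_000)]
        ivs = intergenic_intervals(genes)
        _, curves = decay_profiles(const_track(asm, -0.3), ivs)
        np.testing.assert_allclose(curves.dropna().to_numpy(), -0.3)

    def test_planted_exponential_decay_recovered(self):
        """Curve fit to the per-class profile recovers the planted rate."""
        kappa = 3000.0
        asm = GenomeAssembly([("1A", 2_000_000)])
        genes = [mk_gene(f"g{i}", "1A", i * 80_000, i * 80_000 + 2_000)
                 for i in range(25)]
        mids = np.arange(200_000) * 10 + 5
        starts = np.array([g.interval.start for g in genes])
        ends = np.array([g.interval.end for g in genes])
        d = np.minimum.reduce([np.abs(mids[:, None] - ends[None, :]).min(axis=1),
                               np.abs(starts[None, :] - mids[:, None]).min(axis=1)])
        a = 0.8 * np.exp(-d / kappa)
        dns = DNSTrack(asm, 10, data={"1A": a})
        ivs = intergenic_intervals(genes)
        _, curves = decay_profiles(dns, ivs)
        col = curves.columns[0]
        y = curves[col].dropna().to_numpy()
        x = (np.arange(y.size) + 0.5) * 1000
        from scipy.optimize import curve_fit
        popt, _ = curve_fit(lambda x, A, k, B: A * np.exp(-x / k) + B,
                            x, y, p0=(0.5, 2000.0, 0.0), maxfev=10_000)
        assert popt[1] == pytest.approx(kappa, rel=0.15)


class TestBackground:
    def test_normal_sample_mode_near_mean(self):
        rng = np.random.default_rng(8)
        series = [{"spacing_class": "gt1Mb",
                   "values": rng.normal(-0.017, 0.05, 10_000)}]
        assert background_dns(series, "gt1Mb") == pytest.approx(-0.017, abs=0.005)

    def test_constant_values(self):
        series = [{"spacing_class": "lt10kb", "values": np.full(200, 0.4)}]
        assert background_dns(series, "lt10kb") == pytest.approx(0.4)

    def test_too_few_values_missing(self):
        series = [{"spacing_class": "lt10kb", "values": np.ones(5)}]
        assert np.isnan(background_dns(series, "lt10kb"))


class TestSpacingTests:
    def test_identical_values_p_one(self):
        asm = GenomeAssembly([("1A", 10_000_000)])
        genes = []
        pos = 0
        for i in range(20):
            gap = 50_000 if i % 2 == 0 else 150_000
            genes.append(mk_gene(f"g{i}", "1A", pos, pos + 1000))
            pos += 1000 + gap
        ivs = intergenic_intervals(genes)
        df = spacing_class_tests(const_track(asm, 1.0), ivs, seed=1)
        row = df[df.stratum == "genome"].iloc[0]
        assert row.p == pytest.approx(1.0)

    def test_spacing_dependent_signal_detected(self, rng):
        asm = GenomeAssembly([("1A", 30_000_000)])
        genes = []
        pos = 0
        for i in range(120):
            gap = int(rng.integers(20_000, 80_000)) if i % 2 == 0 \
                else int(rng.integers(120_000, 300_000))
            genes.append(mk_gene(f"g{i}", "1A", pos, pos + 1000))
            pos += 1000 + gap
        ivs = intergenic_intervals(genes)
        # shorter intervals more accessible
        n = -(-30_000_000 // 10)
        data = np.zeros(n)
        for ig in ivs:
            v = 0.5 if len(ig.interval) < 100_000 else -0.2
            b0, b1 = ig.interval.start // 10, (ig.interval.end - 1) // 10
            data[b0:b1 + 1] = v + rng.normal(0, 0.05)
        df = spacing_class_tests(DNSTrack(asm, 10, data={"1A": data}), ivs, seed=2)
        row = df[df.stratum == "genome"].iloc[0]
        assert row.mean_short > row.mean_long
        assert row.p < 0.01


class TestTeScores:
    def test_constant_track(self):
        asm = GenomeAssembly([("1A", 100_000)])
        tes = [TEAnnotation(GenomicInterval("1A", 0, 5000), "RLG_famc1"),
               TEAnnotation(GenomicInterval("1A", 10_000, 14_000), "RLG_famc1")]
        out = te_scores(const_track(asm, 0.25), tes, asm)
        fam = out["by_family"].iloc[0]
        assert fam["mean"] == pytest.approx(0.25)
        assert fam["sd"] == pytest.approx(0.0)

    def test_two_element_family_stats(self):
        asm = GenomeAssembly([("1A", 100_000)])
        data = np.zeros(10_000)
        data[0:500] = 0.1    # TE 1 bins
        data[1000:1400] = 0.3  # TE 2 bins
        dns = DNSTrack(asm, 10, data={"1A": data})
        tes = [TEAnnotation(GenomicInterval("1A", 0, 5000), "DTC_famc3"),
               TEAnnotation(GenomicInterval("1A", 10_000, 14_000), "DTC_famc3")]
        out = te_scores(dns, tes, asm)["by_family"].iloc[0]
        assert out["mean"] == pytest.approx(0.2)
        assert out["sd"] == pytest.approx(np.std([0.1, 0.3], ddof=1))

    def test_order_invariance(self, small_truth, rng):
        asm = small_truth.assembly
        dns = DNSTrack(asm, 10, data={c: rng.normal(size=-(-asm.length(c) // 10))
                                      for c in asm})
        fwd = te_scores(dns, small_truth.tes, asm)["by_family"]
        rev = te_scores(dns, small_truth.tes[::-1], asm)["by_family"]
        pd.testing.assert_frame_equal(fwd, rev)

    def test_planted_family_ordering_recovered(self, mid_pipeline):
        truth, avg = mid_pipeline["truth"], mid_pipeline["avg"]
        out = te_scores(avg, truth.tes, truth.assembly)["per_element"]
        fam_means = out.groupby("family")["mean_dns"].mean()
        effects = {f.family: f.effect for f in truth.config.te_families}
        shared = [f for f in fam_means.index if f in effects]
        got = fam_means[shared].sort_values().index.tolist()
        want = sorted(shared, key=lambda f: effects[f])
        assert got == want


class TestGypsyCorrelation:
    def test_perfect_negative_monotone(self):
        asm = GenomeAssembly([("1A", 2_000_000)])
        n = 200_000
        data = np.repeat(np.linspace(1, 0, 20), 10_000)[:n]
        dns = DNSTrack(asm, 10, data={"1A": data})
        tes = []
        for i in range(20):  # RLG coverage increasing along the chromosome
            start = i * 100_000
            tes.append(TEAnnotation(GenomicInterval("1A", start,
                                                    start + 2000 + 3000 * i),
                                    "RLG_famc1"))
        out = gypsy_dns_correlation(dns, tes, asm, window=100_000, step=100_000)
        rho, _, nwin = out["A"]
        assert rho == pytest.approx(-1.0, abs=0.05)

    def test_no_rlg_windows_undefined(self):
        asm = GenomeAssembly([("1A", 2_000_000)])
        out = gypsy_dns_correlation(const_track(asm), [], asm,
                                    window=100_000, step=100_000)
        assert np.isnan(out["A"][0])

    def test_spearman_matches_rank_oracle(self, rng):
        for n in (5, 6, 8):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            rho, _ = stats.spearmanr(x, y)
            assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-10)


class TestPromoterTe:
    def test_te_overlap_rules(self):
        asm = GenomeAssembly([("1A", 100_000)])
        genes = [mk_gene("g", "1A", 50_000, 55_000, "+")]  # promoter [48100,50100)... cds_start 50100
        cds_start = genes[0].cds_start
        tes = [TEAnnotation(GenomicInterval("1A", cds_start - 1500, cds_start - 800),
                            "DTC_famc3"),      # fully inside promoter
               TEAnnotation(GenomicInterval("1A", cds_start - 2500, cds_start - 1999),
                            "RLG_famc1"),      # 1 bp overlap
               TEAnnotation(GenomicInterval("1A", 10_000, 12_000), "RLC_famc2")]
        df = promoter_te_comparison(const_track(asm), tes, genes, asm)
        within = df.set_index("superfamily")["n_within"]
        assert within["DTC"] == 1 and within["RLG"] == 1
        assert df.set_index("superfamily")["n_outside"]["RLC"] == 1

    def test_proximity_boosted_tes_detected(self, rng):
        asm = GenomeAssembly([("1A", 5_000_000)])
        genes = [mk_gene(f"g{i}", "1A", 100_000 * i + 50_000,
                         100_000 * i + 54_000) for i in range(49)]
        n = -(-5_000_000 // 10)
        data = rng.normal(0, 0.05, n)
        tes = []
        for i, g in enumerate(genes):
            near_s = g.cds_start - 1_000
            tes.append(TEAnnotation(GenomicInterval("1A", near_s, near_s + 800),
                                    "DTM_famc6"))
            far_s = g.interval.start - 40_000
            tes.append(TEAnnotation(GenomicInterval("1A", far_s, far_s + 800),
                                    "DTM_famc6"))
        for te in tes[::2]:  # boost the promoter-proximal ones
            b0, b1 = te.interval.start // 10, (te.interval.end - 1) // 10
            data[b0:b1 + 1] += 0.5
        dns = DNSTrack(asm, 10, data={"1A": data})
        df = promoter_te_comparison(dns, tes, genes, asm)
        row = df[(df.superfamily == "DTM")].iloc[0]
        assert row.mean_within > row.mean_outside
        assert row.p < 0.01


class TestGeneTeProximity:
    def test_no_tes_all_far(self):
        asm = GenomeAssembly([("1A", 100_000)])
        genes = [mk_gene("g", "1A", 50_000, 55_000)]
        df = gene_te_proximity_effect(const_track(asm), pd.Series(dtype=float),
                                      [], genes, asm)
        assert (df["n_near"] == 0).all()

    def test_te_at_zero_distance_is_near(self):
        asm = GenomeAssembly([("1A", 100_000)])
        genes = [mk_gene("g", "1A", 50_000, 55_000)]
        tes = [TEAnnotation(GenomicInterval("1A", 55_000, 56_000), "DTT_famc9")]
        df = gene_te_proximity_effect(const_track(asm), pd.Series(dtype=float),
                                      tes, genes, asm)
        assert df[df.te_set == "any"].iloc[0]["n_near"] == 1

    def test_insertion_penalty_detected(self, rng):
        asm = GenomeAssembly([("1A", 10_000_000)])
        genes, tes, tpm = [], [], {}
        n = -(-10_000_000 // 10)
        data = rng.normal(0, 0.05, n)
        for i in range(100):
            s = 100_000 * i + 40_000
            g = mk_gene(f"g{i}", "1A", s, s + 4_000)
            genes.append(g)
            hit = i % 2 == 0
            if hit:
                tes.append(TEAnnotation(GenomicInterval("1A", s - 1_500, s - 500),
                                        "RLG_famc1"))
                data[s // 10:(s + 4_000) // 10] -= 0.4
                tpm[g.gene_id] = float(10 ** rng.normal(0.2, 0.1))
            else:
                data[s // 10:(s + 4_000) // 10] += 0.2
                tpm[g.gene_id] = float(10 ** rng.normal(1.0, 0.1))
        dns = DNSTrack(asm, 10, data={"1A": data})
        df = gene_te_proximity_effect(dns, pd.Series(tpm), tes, genes, asm)
        for metric in ("gene_body_dns", "log10_tpm"):
            row = df[(df.te_set == "any") & (df.metric == metric)].iloc[0]
            assert row.mean_near < row.mean_far
            assert row.p < 0.01
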