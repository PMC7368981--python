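"""Intergenic spacing classes, DNS decay to interval midpoints, background
accessibility, and TE-centred DNS analyses.

Adjacent-gene spacing is measured between gene-model edges after merging
overlapping genes into occupied blocks; the four spacing classes are
< 10 kb, 10-100 kb, 100 kb - 1 Mb and >= 1 Mb (left-closed boundaries).
Decay profiles lay 1-kb windows from each flanking gene edge inward until
the interval midpoint; the background DNS of a spacing class is the mode
(Gaussian KDE, Silverman bandwidth) of its pooled window values — the
accessibility plateau far from genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .context import IntervalIndex, kde_mode
from .core import DNSTrack, aggregate, window_summary
from .genome import GenomicInterval

SPACING_CLASSES = ("lt10kb", "10to100kb", "100kbto1Mb", "gt1Mb")


def spacing_class(length: int) -> str:
    if length < 10_000:
        return "lt10kb"
    if length < 100_000:
        return "10to100kb"
    if length < 1_000_000:
        return "100kbto1Mb"
    return "gt1Mb"


@dataclass(frozen=True)
class IntergenicInterval:
    interval: GenomicInterval
    left_gene: str
    right_gene: str
    spacing_class: str
    segment: str | None = None


def merged_gene_blocks(genes) -> dict[str, list[tuple[int, int, str]]]:
    """Per-chromosome occupied blocks from possibly overlapping gene models.

    Returns chrom -> sorted (start, end, representative gene_id) blocks.
    """
    by_chrom: dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.interval.start, g.interval.end, g.gene_id))
    out = {}
    for chrom, items in by_chrom.items():
        items.sort()
        merged = [list(items[0])]
        for s, e, gid in items[1:]:
            if s < merged[-1][1]:  # overlap -> one occupied block
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e, gid])
        out[chrom] = [tuple(x) for x in merged]
    return out


def intergenic_intervals(genes, segments=None) -> list[IntergenicInterval]:
    """One interval per adjacent pair of occupied gene blocks.

    Chromosome-terminal gaps are excluded. The segment label, when a
    segment table is given, is that of the interval midpoint.
    """
    blocks = merged_gene_blocks(genes)
    out: list[IntergenicInterval] = []
    for chrom, bl in blocks.items():
        if len(bl) < 2:
            warnings.warn(f"chromosome {chrom} has fewer than 2 gene blocks")
            continue
        for (s1, e1, g1), (s2, e2, g2) in zip(bl, bl[1:]):
            if e1 >= s2:
                continue
            iv = GenomicInterval(chrom, e1, s2)
            seg = None
            if segments is not None and chrom in segments.chromosomes:
                seg = segments.label_at(chrom, iv.midpoint)
            out.append(IntergenicInterval(iv, g1, g2, spacing_class(len(iv)), seg))
    return out


def decay_profiles(dns: DNSTrack, intervals, window: int = 1000):
    """1-kb-window DNS series from each gene edge toward the midpoint.

    Each intergenic interval contributes two series (left flank inward,
    right flank inward); windows per side = floor((length/2)/window), so
    intervals shorter than 2 kb contribute none. Returns (per-series list
    of arrays with metadata, per-class mean curve DataFrame indexed by
    window index).
    """
    series = []
    for ig in intervals:
        iv = ig.interval
        k = (len(iv) // 2) // window
        if k == 0:
            continue
        left = [GenomicInterval(iv.chrom, iv.start + i * window,
                                iv.start + (i + 1) * window) for i in range(k)]
        right = [GenomicInterval(iv.chrom, iv.end - (i + 1) * window,
                                 iv.end - i * window) for i in range(k)]
        for side, ivs in (("left", left), ("right", right)):
            vals = aggregate(dns, ivs, "mean")
            series.append({"spacing_class": ig.spacing_class, "side": side,
                           "segment": ig.segment, "values": vals})
    curves = {}
    for cls in SPACING_CLASSES:
        arrs = [s["values"] for s in series if s["spacing_class"] == cls]
        if not arrs:
            continue
        kmax = max(a.size for a in arrs)
        sums = np.zeros(kmax)
        cnts = np.zeros(kmax)
        for a in arrs:
            ok = np.isfinite(a)
            sums[:a.size][ok] += a[ok]
            cnts[:a.size][ok] += 1
        with np.errstate(invalid="ignore"):
            curves[cls] = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    kmax = max((c.size for c in curves.values()), default=0)
    frame = pd.DataFrame({cls: np.concatenate([c, np.full(kmax - c.size, np.nan)])
                          for cls, c in curves.items()})
    frame.index.name = "window_index"
    return series, frame


def background_dns(series, cls: str, min_values: int = 100) -> float:
    """Background (plateau) DNS of a spacing class: KDE mode of its pooled
    1-kb window values. nan when fewer than min_values windows."""
    vals = np.concatenate([s["values"] for s in series
                           if s["spacing_class"] == cls] or [np.array([])])
    vals = vals[np.isfinite(vals)]
    if vals.size < min_values:
        return float("nan")
    if np.ptp(vals) == 0:
        return float(vals[0])
    return kde_mode(vals, log_scale=False)


def spacing_class_tests(dns: DNSTrack, intervals, seed: int = 0,
                        boundary: int = 100_000) -> pd.DataFrame:
    """Mann-Whitney comparisons of interval mean DNS between short
    (< boundary) and long (>= boundary) spacing classes, genome-wide and
    within the distal (R1+R3) and pericentromeric (C) strata, on random
    equal-size subsamples."""
    rng = np.random.default_rng(seed)
    means = aggregate(dns, [ig.interval for ig in intervals], "mean")
    lens = np.array([len(ig.interval) for ig in intervals])
    segs = np.array([ig.segment or "NA" for ig in intervals])
    rows = []
    strata = {"genome": np.ones(len(intervals), dtype=bool),
              "distal": np.isin(segs, ("R1", "R3")),
              "pericentromeric": segs == "C"}
    for name, sel in strata.items():
        short = means[sel & (lens < boundary) & np.isfinite(means)]
        long_ = means[sel & (lens >= boundary) & np.isfinite(means)]
        if short.size == 0 or long_.size == 0:
            continue
        n = min(short.size, long_.size)
        s = rng.choice(short, n, replace=False)
        l = rng.choice(long_, n, replace=False)
        if np.ptp(np.concatenate([s, l])) == 0:
            U, p = float(n * n / 2), 1.0
        else:
            U, p = stats.mannwhitneyu(s, l, alternative="two-sided")
        rows.append({"stratum": name, "n_per_group": n,
                     "mean_short": float(s.mean()), "mean_long": float(l.mean()),
                     "U": float(U), "p": float(p)})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- TEs

def te_scores(dns: DNSTrack, tes, assembly) -> pd.DataFrame:
    """Mean and sample SD of per-element mean DNS by family, superfamily
    and subgenome.

    The per-element statistic is the unweighted mean of the 10-bp bins
    across the element's span; family statistics are across elements.
    """
    means = aggregate(dns, [t.interval for t in tes], "mean")
    df = pd.DataFrame({
        "family": [t.family for t in tes],
        "superfamily": [t.superfamily for t in tes],
        "te_class": [str(t.te_class) for t in tes],
        "subgenome": [assembly.genome_of(t.chrom) for t in tes],
        "mean_dns": means,
    })
    def summarize(grp_cols):
        g = (df.dropna(subset=["mean_dns"])
               .groupby(grp_cols)["mean_dns"]
               .agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count")
               .reset_index())
        return g
    return {"per_element": df,
            "by_family": summarize(["subgenome", "superfamily", "family"]),
            "by_superfamily": summarize(["subgenome", "superfamily"])}


def _covered_fraction_track(intervals, assembly, bin_width):
    """Per-bin fraction of bp covered by the union of intervals."""
    from .core import BinTrack
    track = BinTrack(assembly, bin_width)
    for chrom in assembly:
        L = assembly.length(chrom)
        cov = np.zeros(track.n_bins(chrom))
        ivs = sorted((iv.start, iv.end) for iv in intervals if iv.chrom == chrom)
        merged = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            b0, b1 = s // bin_width, (e - 1) // bin_width
            for b in range(b0, b1 + 1):
                lo = max(s, b * bin_width)
                hi = min(e, min((b + 1) * bin_width, L))
                cov[b] += hi - lo
        widths = np.full(track.n_bins(chrom), bin_width, dtype=float)
        if L % bin_width:
            widths[-1] = L % bin_width
        track.data[chrom] = cov / widths
    return track


def gypsy_dns_correlation(dns: DNSTrack, tes, assembly, window: int = 1_000_000,
                          step: int = 200_000, superfamily: str = "RLG"):
    """Spearman rho between Gypsy (RLG) covered-bp fraction and mean DNS in
    sliding windows, per subgenome.

    Only windows containing the superfamily (fraction > 0) enter; a
    subgenome with < 3 eligible windows reports nan.
    """
    sel = [t.interval for t in tes if t.superfamily == superfamily]
    frac_track = _covered_fraction_track(sel, assembly, dns.bin_width)
    ivs, dns_means, _ = window_summary(dns, window, step)
    fracs = aggregate(frac_track, ivs, "mean")
    out = {}
    for sub in assembly.subgenomes:
        idx = [i for i, iv in enumerate(ivs)
               if assembly.genome_of(iv.chrom) == sub and fracs[i] > 0
               and np.isfinite(dns_means[i])]
        if len(idx) < 3:
            out[sub] = (float("nan"), float("nan"), len(idx))
            continue
        rho, p = stats.spearmanr(fracs[idx], dns_means[idx])
        out[sub] = (float(rho), float(p), len(idx))
    return out


def _promoter_index(genes, assembly, radius):
    by_chrom: dict[str, list] = {}
    for i, g in enumerate(genes):
        if g.strand == "+":
            s, e = g.cds_start - radius, g.cds_start
        else:
            s, e = g.cds_end, g.cds_end + radius
        s, e = max(0, s), min(assembly.length(g.chrom), e)
        if s < e:
            by_chrom.setdefault(g.chrom, []).append((s, e, i))
    return IntervalIndex(by_chrom)


def promoter_te_comparison(dns: DNSTrack, tes, genes, assembly,
                           radius: int = 2000) -> pd.DataFrame:
    """Per-superfamily, per-subgenome DNS of TEs overlapping a 2-kb
    promoter (>= 1 bp) vs TEs outside, with Mann-Whitney p."""
    prom = _promoter_index(genes, assembly, radius)
    means = aggregate(dns, [t.interval for t in tes], "mean")
    within = np.zeros(len(tes), dtype=bool)
    for i, t in enumerate(tes):
        # overlap by >= 1 bp: any covered point; check both ends and a
        # containing promoter via the index
        iv = t.interval
        within[i] = (prom.covering(iv.chrom, iv.start) >= 0 or
                     prom.covering(iv.chrom, iv.end - 1) >= 0 or
                     _any_inside(prom, iv))
    rows = []
    df = pd.DataFrame({"superfamily": [t.superfamily for t in tes],
                       "subgenome": [assembly.genome_of(t.chrom) for t in tes],
                       "mean_dns": means, "within": within})
    for (sub, sf), grp in df.dropna(subset=["mean_dns"]).groupby(["subgenome", "superfamily"]):
        a = grp.loc[grp.within, "mean_dns"].to_numpy()
        b = grp.loc[~grp.within, "mean_dns"].to_numpy()
        row = {"subgenome": sub, "superfamily": sf,
               "n_within": a.size, "n_outside": b.size,
               "mean_within": float(a.mean()) if a.size else float("nan"),
               "mean_outside": float(b.mean()) if b.size else float("nan")}
        if a.size >= 2 and b.size >= 2 and np.ptp(np.concatenate([a, b])) > 0:
            U, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            row.update(U=float(U), p=float(p))
        else:
            row.update(U=float("nan"), p=float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def _any_inside(index: IntervalIndex, iv: GenomicInterval) -> bool:
    """Whether any indexed interval starts inside iv (overlap not caught by
    endpoint queries)."""
    if iv.chrom not in index._starts:
        return False
    s = index._starts[iv.chrom]
    i0 = int(np.searchsorted(s, iv.start, side="left"))
    i1 = int(np.searchsorted(s, iv.end, side="left"))
    return i1 > i0


def gene_te_proximity_effect(dns: DNSTrack, expression, tes, genes, assembly,
                             radius: int = 2000) -> pd.DataFrame:
    """Gene-body DNS and log10 expression for genes with vs without a TE
    within `radius` bp of the gene model, stratified by TE class."""
    body = aggregate(dns, [g.interval for g in genes], "mean")
    log_expr = np.array([np.log10(expression[g.gene_id])
                         if g.gene_id in expression.index and expression[g.gene_id] > 0
                         else np.nan for g in genes])
    rows = []
    for label, sel_tes in (("any", tes),
                           ("class1", [t for t in tes if t.te_class == 1]),
                           ("class2", [t for t in tes if t.te_class == 2])):
        idx = IntervalIndex.from_intervals([t.interval for t in sel_tes])
        near = np.zeros(len(genes), dtype=bool)
        for i, g in enumerate(genes):
            lo = max(0, g.interval.start - radius)
            hi = min(assembly.length(g.chrom), g.interval.end + radius)
            iv = GenomicInterval(g.chrom, lo, hi)
            near[i] = (idx.covering(g.chrom, lo) >= 0 or
                       idx.covering(g.chrom, hi - 1) >= 0 or _any_inside(idx, iv))
        for metric, vals in (("gene_body_dns", body), ("log10_tpm", log_expr)):
            a = vals[near & np.isfinite(vals)]
            b = vals[~near & np.isfinite(vals)]
            row = {"te_set": label, "metric": metric,
                   "n_near": a.size, "n_far": b.size,
                   "mean_near": float(a.mean()) if a.size else float("nan"),
                   "mean_far": float(b.mean()) if b.size else float("nan")}
            if a.size >= 2 and b.size >= 2 and np.ptp(np.concatenate([a, b])) > 0:
                U, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                row.update(U=float(U), p=float(p))
            else:
                row.update(U=float("nan"), p=float("nan"))
            rows.append(row)
    return pd.DataFrame(rows)
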