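"""Gene-centred DNS profiles and homoeolog expression-bias analysis.

All windows are strand-oriented and anchored at the CDS start (for minus
strand genes the anchor is cds_end and offsets run leftward), so profiles
from the two strands superimpose. The a/b/c/d regions are the four 500-bp
intervals (-1000,-500], (-500,0], (0,+500], (+500,+1000] around the CDS
start used to compare promoter/5' accessibility across subgenomes within
homoeologous triplets.

Triplet expression categories follow the relative-contribution scheme for
allohexaploid 1:1:1 homoeolog sets: the triplet's (rA, rB, rD) fractions
are assigned to the nearest of seven centroids — balanced (1/3,1/3,1/3),
single-homoeolog dominant (1 on one subgenome), and single-homoeolog
suppressed (0 on one subgenome, 1/2 on the others). The centroid table is
configurable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import DNSTrack, aggregate
from .genome import GenomicInterval


def _anchor(gene) -> int:
    """CDS-start anchor in genomic coordinates (strand-aware)."""
    return gene.cds_start if gene.strand == "+" else gene.cds_end


def _oriented_window(gene, u: int, v: int) -> tuple[int, int]:
    """Map the gene-oriented window [u, v) (0 = CDS start, negative =
    upstream) to genomic coordinates."""
    if gene.strand == "+":
        return gene.cds_start + u, gene.cds_start + v
    return gene.cds_end - v, gene.cds_end - u


def genic_partition_scores(dns: DNSTrack, genes, assembly) -> pd.DataFrame:
    """Per-gene mean DNS for the standard genic partitions.

    Columns: gene_body, upstream_500, upstream_2kb, downstream_2kb, plus a
    truncated flag when a flank window runs off the chromosome (scored over
    the existing part). Intergenic space is handled by
    intergenic_partition_scores.
    """
    windows = {"upstream_500": (-500, 0), "upstream_2kb": (-2000, 0),
               "downstream_2kb": None}
    rows = {}
    truncated = np.zeros(len(genes), dtype=bool)
    ivs_body = [g.interval for g in genes]
    rows["gene_body"] = aggregate(dns, ivs_body, "mean")
    for name, uv in windows.items():
        ivs = []
        for i, g in enumerate(genes):
            L = assembly.length(g.chrom)
            if name == "downstream_2kb":
                # 2 kb past the CDS end, gene-oriented
                cds_len = g.cds_end - g.cds_start
                s, e = _oriented_window(g, cds_len, cds_len + 2000)
            else:
                s, e = _oriented_window(g, *uv)
            cs, ce = max(0, s), min(L, e)
            if (cs, ce) != (s, e):
                truncated[i] = True
            ivs.append(GenomicInterval(g.chrom, cs, ce) if cs < ce else None)
        vals = np.full(len(genes), np.nan)
        present = [iv for iv in ivs if iv is not None]
        if present:
            agg = aggregate(dns, present, "mean")
            j = 0
            for i, iv in enumerate(ivs):
                if iv is not None:
                    vals[i] = agg[j]
                    j += 1
        rows[name] = vals
    df = pd.DataFrame(rows, index=[g.gene_id for g in genes])
    df["truncated"] = truncated
    return df


def intergenic_partition_scores(dns: DNSTrack, genes, assembly,
                                flank: int = 2000) -> pd.DataFrame:
    """Mean DNS per intergenic block (complement of gene models +- flank)."""
    by_chrom: dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(
            (max(0, g.interval.start - flank),
             min(assembly.length(g.chrom), g.interval.end + flank)))
    rows = []
    for chrom in assembly:
        L = assembly.length(chrom)
        occupied = sorted(by_chrom.get(chrom, []))
        merged = []
        for s, e in occupied:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        pos = 0
        for s, e in merged + [[L, L]]:
            if pos < s:
                rows.append(GenomicInterval(chrom, pos, s))
            pos = max(pos, e)
    vals = aggregate(dns, rows, "mean") if rows else np.array([])
    return pd.DataFrame({"chrom": [iv.chrom for iv in rows],
                         "start": [iv.start for iv in rows],
                         "end": [iv.end for iv in rows],
                         "mean_dns": vals})


def metagene(dns: DNSTrack, genes, flank: int = 1000) -> pd.DataFrame:
    """Mean DNS in 10-bp steps around the CDS start, strand-oriented.

    Offsets run -flank .. +flank-10 (negative = upstream). Genes whose
    window runs off the chromosome contribute only their covered offsets.
    Returns a frame indexed by offset with columns mean_dns and n_genes.
    """
    w = dns.bin_width
    if flank % w:
        raise ValueError("flank must be a multiple of the bin width")
    offsets = np.arange(-flank, flank, w)
    sums = np.zeros(offsets.size)
    counts = np.zeros(offsets.size, dtype=np.int64)
    any_gene = False
    for g in genes:
        a = _anchor(g)
        if g.strand == "+":
            wstart = a + offsets
        else:
            wstart = a - offsets - w
        bidx = (wstart + w // 2) // w
        n = dns.n_bins(g.chrom)
        ok = (bidx >= 0) & (bidx < n)
        bi = bidx[ok]
        unmasked = ~dns.mask[g.chrom][bi]
        vals = dns.data[g.chrom][bi]
        idx = np.flatnonzero(ok)[unmasked]
        sums[idx] += vals[unmasked]
        counts[idx] += 1
        any_gene = True
    if not any_gene:
        raise ValueError("no eligible genes for metagene profile")
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({"mean_dns": mean, "n_genes": counts}, index=offsets)


ABCD_WINDOWS = {"a": (-1000, -500), "b": (-500, 0), "c": (0, 500), "d": (500, 1000)}


def region_abcd(dns: DNSTrack, genes, assembly) -> pd.DataFrame:
    """Per-gene mean DNS in regions a/b/c/d around the CDS start.

    Genes whose full -1 kb .. +1 kb window does not fit on the chromosome
    are excluded (fixed-width comparability across subgenomes).
    """
    eligible = []
    for g in genes:
        s, e = _oriented_window(g, -1000, 1000)
        if s >= 0 and e <= assembly.length(g.chrom):
            eligible.append(g)
    out = {}
    for name, (u, v) in ABCD_WINDOWS.items():
        ivs = [GenomicInterval(g.chrom, *_oriented_window(g, u, v)) for g in eligible]
        out[name] = aggregate(dns, ivs, "mean") if ivs else np.array([])
    return pd.DataFrame(out, index=[g.gene_id for g in eligible])


def expression_dns_correlation(scores: pd.Series, expression: pd.Series,
                               min_tpm: float = 0.1, pseudocount: float = 0.0):
    """Pearson r between log10(tpm) and a per-gene DNS score.

    Only expressed genes (mean tpm >= min_tpm) enter; returns (r, p, n);
    nan when fewer than 3 genes or a constant side.
    """
    common = scores.index.intersection(expression.index)
    tpm = expression.loc[common]
    sc = scores.loc[common]
    keep = (tpm >= min_tpm) & sc.notna()
    tpm, sc = tpm[keep], sc[keep]
    if len(tpm) < 3 or sc.std() == 0 or tpm.std() == 0:
        return float("nan"), float("nan"), int(len(tpm))
    r, p = stats.pearsonr(np.log10(tpm + pseudocount), sc)
    return float(r), float(p), int(len(tpm))


DEFAULT_CENTROIDS = {
    "balanced": (1 / 3, 1 / 3, 1 / 3),
    "A.dominant": (1.0, 0.0, 0.0),
    "B.dominant": (0.0, 1.0, 0.0),
    "D.dominant": (0.0, 0.0, 1.0),
    "A.suppressed": (0.0, 0.5, 0.5),
    "B.suppressed": (0.5, 0.0, 0.5),
    "D.suppressed": (0.5, 0.5, 0.0),
}


def categorize_triplets(triplets: pd.DataFrame, expression: pd.Series,
                        min_sum_tpm: float = 0.5,
                        centroids: dict | None = None) -> pd.DataFrame:
    """Assign each homoeologous triplet an expression-bias category.

    Triplets with total expression below min_sum_tpm, or with a missing
    homoeolog, are dropped. Relative contributions (rA, rB, rD) go to the
    nearest centroid by Euclidean distance; exact ties resolve to balanced.
    """
    if centroids is None:
        centroids = DEFAULT_CENTROIDS
    names = list(centroids)
    C = np.array([centroids[k] for k in names])
    rows = []
    import warnings as _w
    for t in triplets.itertuples(index=False):
        ids = (t.gene_A, t.gene_B, t.gene_D)
        if not all(g in expression.index for g in ids):
            _w.warn(f"triplet {ids} has missing expression; skipped")
            continue
        tpm = np.array([expression[g] for g in ids], dtype=float)
        total = tpm.sum()
        if total < min_sum_tpm:
            continue
        r = tpm / total
        d = np.sqrt(((C - r) ** 2).sum(axis=1))
        best = float(d.min())
        tied = [names[i] for i in range(len(names)) if d[i] <= best + 1e-12]
        category = "balanced" if len(tied) > 1 and "balanced" in tied else tied[0]
        rows.append({"gene_A": ids[0], "gene_B": ids[1], "gene_D": ids[2],
                     "rA": r[0], "rB": r[1], "rD": r[2], "sum_tpm": total,
                     "category": category})
    return pd.DataFrame(rows)


def triplet_bias_tests(categories: pd.DataFrame, abcd: pd.DataFrame) -> pd.DataFrame:
    """Kruskal-Wallis across the three subgenomes per region and category,
    plus pairwise Mann-Whitney with Benjamini-Hochberg adjustment.

    abcd is the per-gene region a/b/c/d table; a triplet contributes its
    three homoeologs' values to their respective subgenome groups.
    """
    genome_cols = {"A": "gene_A", "B": "gene_B", "D": "gene_D"}
    rows = []
    pairwise_rows = []
    for category, grp in categories.groupby("category"):
        for region in ("a", "b", "c", "d"):
            groups = {}
            for genome, col in genome_cols.items():
                ids = [g for g in grp[col] if g in abcd.index]
                vals = abcd.loc[ids, region].dropna().to_numpy()
                if vals.size:
                    groups[genome] = vals
            if len(groups) < 2 or any(v.size < 2 for v in groups.values()):
                continue
            H, p = stats.kruskal(*groups.values())
            rows.append({"category": category, "region": region,
                         "H": float(H), "p": float(p),
                         "n": sum(v.size for v in groups.values())})
            keys = sorted(groups)
            for i in range(len(keys)):
                for j in range(i + 1, len(keys)):
                    U, pp = stats.mannwhitneyu(groups[keys[i]], groups[keys[j]],
                                               alternative="two-sided")
                    pairwise_rows.append({"category": category, "region": region,
                                          "pair": f"{keys[i]}-{keys[j]}",
                                          "U": float(U), "p": float(pp)})
    kw = pd.DataFrame(rows)
    pw = pd.DataFrame(pairwise_rows)
    if len(pw):
        pw["p_adj"] = multipletests(pw["p"], method="fdr_bh")[1]
    kw.attrs["pairwise"] = pw
    return kw
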